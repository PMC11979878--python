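"""Delimited-text input/output and deterministic test fixtures.

Input is a single long-format table (CSV/TSV): one numeric response column,
one or two categorical factor columns and any number of numeric covariate
columns, declared by name in an :class:`AnalysisConfig`.  Two factor columns
are crossed into a single cell index ordered first-factor slow, matching the
Kronecker ordering of :func:`hetmctp.contrasts.factorial_contrast`.  Results
are written back as CSV with a commented header block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .bootstrap import BootResult
from .mctp import MctpTResult
from .model import AncovaData


@dataclass
class AnalysisConfig:
    """Column roles and method settings for a delimited-text analysis."""

    response: str
    factors: List[str]
    covariates: List[str] = field(default_factory=list)
    method: str = "t"
    contrast: str = "dunnett"
    alpha: float = 0.05
    df_rule: str = "mean"
    nboot: int = 10000
    seed: Optional[int] = None

    def __post_init__(self):
        if isinstance(self.factors, str):
            self.factors = [self.factors]
        if not 1 <= len(self.factors) <= 2:
            raise ValueError("need exactly 1 or 2 factor columns")


def _first_appearance_order(values: pd.Series) -> list:
    seen = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen


def read_table(path: Union[str, Path], config: AnalysisConfig) -> AncovaData:
    """Read a CSV/TSV file into an :class:`AncovaData`.

    Missing values anywhere in the declared columns are a hard error naming
    the offending rows.  With two factors, cells are labelled
    ``"<level1>:<level2>"`` and ordered first factor slow; every cell must be
    non-empty.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    cols = [config.response, *config.factors, *config.covariates]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"columns not found in {path.name}: {missing_cols}")
    sub = df[cols]
    na_rows = sub.index[sub.isna().any(axis=1)].tolist()
    if na_rows:
        raise ValueError(
            f"missing values in {path.name} at row(s) {na_rows} "
            "(0-based, excluding the header)"
        )
    for c in [config.response, *config.covariates]:
        if not np.issubdtype(sub[c].dtype, np.number):
            raise ValueError(f"column {c!r} must be numeric")

    if len(config.factors) == 1:
        groups = sub[config.factors[0]].astype(str).to_numpy()
        order = None
        structure = None
    else:
        f1 = sub[config.factors[0]].astype(str)
        f2 = sub[config.factors[1]].astype(str)
        lev1 = _first_appearance_order(f1)
        lev2 = _first_appearance_order(f2)
        groups = (f1 + ":" + f2).to_numpy()
        order = [f"{u}:{v}" for u in lev1 for v in lev2]  # factor 1 slow
        observed = set(groups.tolist())
        empty = [c for c in order if c not in observed]
        if empty:
            raise ValueError(f"empty factor cells: {empty}")
        structure = (len(lev1), len(lev2))
    return AncovaData(
        y=sub[config.response].to_numpy(dtype=float),
        groups=groups,
        covariates=sub[config.covariates].to_numpy(dtype=float)
        if config.covariates else None,
        factor_structure=structure,
        group_order=order,
    )


def write_results(result: Union[MctpTResult, BootResult],
                  path: Union[str, Path]) -> None:
    """Write an MCTP result as CSV with a ``#``-commented header block."""
    path = Path(path)
    is_boot = isinstance(result, BootResult)
    lines = ["# hetmctp result"]
    lines.append(f"# method: {'wild-bootstrap' if is_boot else 'multivariate-t'}")
    if is_boot:
        lines.append(f"# nboot: {result.nboot}")
        lines.append(f"# seed: {result.seed}")
    else:
        lines.append(f"# df_rule: {result.df_rule}")
        lines.append(f"# df: {result.df_used!r}")
    lines.append(f"# alpha: {result.alpha!r}")
    lines.append(f"# T0: {result.T0!r}")
    lines.append(f"# critical: {result.critical!r}")
    lines.append(f"# reject_global: {result.reject_global}")
    df = pd.DataFrame({
        "contrast": result.row_labels,
        "estimate": result.estimates,
        "lower": result.sci[:, 0],
        "upper": result.sci[:, 1],
        "statistic": result.statistics,
        "p_adjusted": result.p_adjusted,
    })
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a results file written by :func:`write_results` (the header
    block is exposed in ``df.attrs['header']``)."""
    path = Path(path)
    header = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                header[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    df.attrs["header"] = header
    return df


def make_fixture(kind: str, seed: int = 0) -> AncovaData:
    """Small deterministic datasets with known generating parameters.

    ``welch_pair``: two groups, no covariates, unequal variances — the MCTP
    reduces to a Welch two-sample comparison.
    ``three_group``: three groups of 8, one covariate.
    ``factorial_2x6``: a synthetic two-way layout shaped like a toxicology
    dose (6 levels) x sex (2 levels) trial with 10 subjects per cell and
    2 covariates; all values are generated, not real data.
    """
    rng = np.random.default_rng(seed)
    if kind == "welch_pair":
        n1, n2 = 10, 14
        y = np.concatenate([
            5.0 + 2.0 * rng.standard_normal(n1),
            6.0 + 0.7 * rng.standard_normal(n2),
        ])
        groups = np.repeat(["ctrl", "trt"], [n1, n2])
        return AncovaData(y=y, groups=groups)
    if kind == "three_group":
        n = 8
        codes = np.repeat([0, 1, 2], n)
        x = rng.normal(7.0, 1.0, size=(3 * n, 1))
        sigma = np.array([1.0, 2.0, 0.5])[codes]
        y = 7.0 + 0.8 * x[:, 0] + sigma * rng.standard_normal(3 * n)
        return AncovaData(y=y, groups=codes, covariates=x)
    if kind == "factorial_2x6":
        doses = ["0", "50", "100", "250", "500", "1000"]
        sexes = ["m", "f"]
        cells = [f"{s}:{d}" for s in sexes for d in doses]
        n_cell = 10
        groups = np.repeat(cells, n_cell)
        N = len(groups)
        M = np.column_stack([
            rng.normal(15.0, 2.0, N),       # baseline measurement
            rng.normal(80.0, 12.0, N),      # weight change
        ])
        sex_eff = np.repeat([1.5, 0.0], 6 * n_cell)
        sigma = rng.uniform(0.8, 2.5, 12).repeat(n_cell)
        y = 16.0 + sex_eff - 0.04 * M[:, 0] + 0.01 * M[:, 1] \
            + sigma * rng.standard_normal(N)
        return AncovaData(y=y, groups=groups, covariates=M,
                          factor_structure=(2, 6), group_order=cells)
    raise ValueError(f"unknown fixture kind {kind!r}")
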