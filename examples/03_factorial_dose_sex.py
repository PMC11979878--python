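"""Two-way factorial analysis: dose x sex with two covariates.

A synthetic toxicology-shaped trial (6 dose levels x 2 sexes, 10 animals per
cell, baseline and weight-change covariates; the generator builds in a sex
effect but no dose effect).  Main effects and the interaction are tested with
Kronecker-product contrasts on the 12 cell effects: dose levels are compared
to the dose grand mean after averaging over sex, and vice versa.
"""

from hetmctp import factorial_contrast, make_fixture, mctp_t_test

data = make_fixture("factorial_2x6", seed=1)
print(f"cells: {data.n_groups} (= 2 x 6), N = {data.n_obs}, "
      f"covariates = {data.n_covariates}\n")

for name, effect in [("sex", "main_first"), ("dose", "main_second"),
                     ("dose x sex", "interaction")]:
    C = factorial_contrast((2, 6), effect)
    res = mctp_t_test(data, C, df_rule="min")
    print(f"{name:>11}: T0 = {res.T0:6.3f}, critical = {res.critical:5.3f}, "
          f"min adjusted p = {res.p_adjusted.min():6.4f} "
          f"-> {'reject' if res.reject_global else 'retain'}")

print("\nOnly the sex main effect should be rejected: the generator shifts"
      "\nmale cells by +1.5 and leaves dose levels exchangeable.")
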