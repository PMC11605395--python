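"""Generate a synthetic study cohort and re-estimate its parameters.

The generator emulates the observational design (sparse pre-injection
troughs, a rich-sampled subset, LLOQ censoring); the Laplace estimator
then recovers clearance, the fast-pathway fraction and the slow absorption
rate from the simulated concentrations.
"""

import time

import rilpk as rk

params = rk.published_parameters()
re_spec = rk.RandomEffectsSpec(
    omega_ka_slow=rk.omega_from_cv(82.7),
    omega_CL=rk.omega_from_cv(25.9),
    omega_eta_Ffast=0.232,
    sigma_add_oral=18.0,
    sigma_prop_im=0.18,
)

spec = rk.CohortSpec(n_subjects=24, n_rich=20, median_follow_up_weeks=48.0)
table, subjects, truth = rk.generate_cohort(spec, params, re_spec, seed=3)
print(f"cohort: {table.n_subjects} subjects, {table.n_observations} "
      f"observations {table.n_observations_by_route()}")

init = params.with_(CL=5.0, F_im_fast=0.35, ka_slow=0.0004)
t0 = time.time()
res = rk.fit(
    table, init, re_spec,
    estimate=("CL", "F_im_fast", "ka_slow",
              "omega_CL", "omega_eta_Ffast", "omega_ka_slow"),
    maxiter=60,
)
print(f"fit in {time.time() - t0:.0f}s, OFV {res.ofv:.1f}, "
      f"converged={res.converged}\n")

tv = {"CL": 6.74, "F_im_fast": 0.276, "ka_slow": 0.000229}
print(f"{'parameter':18s} {'estimate':>10s} {'truth':>10s} {'RSE%':>6s}")
for name in res.estimates:
    t = tv.get(name, "")
    rse = res.rse_percent.get(name, float('nan'))
    print(f"{name:18s} {res.estimates[name]:10.4g} {t!s:>10s} {rse:6.1f}")
print("\nEstimates should sit within a few (tens of) percent of truth; "
      "ka_slow is the least precise, mirroring its dominant 82.7% CV.")
print(f"\nF_im_fast eta-shrinkage: "
      f"{rk.shrinkage(res.eb_effects('Ffast'), res.re_spec.omega_eta_Ffast):.0f}%")
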