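"""Growth-kinetics validation screen: mu_max, IIE and RSGR for one clone.

Simulates the plate-reader experiment behind the screen's validation stage:
4 biological replicates of a candidate overexpression clone and the wild
type, each at 0% and 0.5% (v/v) n-butanol, then scores the clone with

    IIE  = (T_clone / T_wt - 1) * 100,   T = mu_max(0.5%) / mu_max(0%)
    RSGR = (mu_clone,0 / mu_wt,0 - 1) * 100

with a two-sample t-test on the per-replicate tolerance ratios.
"""

import numpy as np

from butolscreen import kinetics, synthdata

rng = np.random.default_rng(7)
times = np.arange(0.0, 24.01, 0.25)  # 15-min sampling for 24 h

TRUE_IIE = 49.1          # encoded effect, percent
T_WT = 0.5               # wild-type tolerance ratio at 0.5% butanol
MU_WT0 = 0.6             # wild-type mu_max without solvent, 1/h
t_clone = T_WT * (1 + TRUE_IIE / 100)

mu = {("WT", 0.0): MU_WT0, ("WT", 0.5): MU_WT0 * T_WT,
      ("clone", 0.0): MU_WT0, ("clone", 0.5): MU_WT0 * t_clone}
curves = {"WT": [], "clone": []}
for strain in ("WT", "clone"):
    for cond in (0.0, 0.5):
        for rep in range(1, 5):
            curves[strain].append(synthdata.simulate_growth(
                mu_max=mu[(strain, cond)], lag=2.0, carrying_capacity=1.3,
                times=times, noise_sd=0.005, seed=int(rng.integers(2**31)),
                od0=0.05, strain_id=strain, condition=cond, replicate=rep))

fit = kinetics.fit_mu_max(curves["WT"][0], od_band=(0.08, 0.45))
print(f"example fit: WT rep 1 at 0% -> mu_max {fit.mu_max:.3f}/h over "
      f"{fit.window[0]:.1f}-{fit.window[1]:.1f} h, R^2 {fit.r_squared:.4f}")
print("   (the fixed-OD-band fit under-reads every strain by the same "
      "factor, which cancels in the tolerance ratios below)")

result = kinetics.screen_gene(curves["clone"], curves["WT"],
                              gene_id="candidate", od_band=(0.08, 0.45))
print(f"IIE  = {result.iie:+.1f} +- {result.iie_sd:.1f} %   (encoded {TRUE_IIE}%)")
print(f"RSGR = {result.rsgr:+.1f} +- {result.rsgr_sd:.1f} %   (encoded 0%)")
print(f"p = {result.p_value:.2e} over {result.n_replicates} replicates "
      f"-> significant: {result.significant}")
print("-> the clone's solvent tolerance improved ~49% relative to wild type "
      "with no growth penalty at 0% butanol")
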