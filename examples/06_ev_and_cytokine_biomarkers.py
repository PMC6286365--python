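"""Downstream biomarker statistics: EV release and liver cytokines.

An in-vitro EV-release study (4 doses + vehicle, 4 replicates) is fitted
with the shared dose-response machinery; an in-vivo style group comparison
(saline / inflammation / treated, n = 5) runs one-way ANOVA with Tukey's
post hoc and a percent-reduction estimate; a qPCR table is collapsed to
2^-ddCt fold-changes against the saline group.
"""

from qhtskit.biomarkers import (
    GroupedCounts,
    anova_tukey,
    ddct_fold_change,
    ev_dose_response,
    percent_reduction,
)
from qhtskit.synth import EmaxModel, simulate_ev_study, simulate_qpcr

# dose-dependent inhibition of EV release from cultured astrocytes
study = simulate_ev_study(
    effect_model=EmaxModel(vehicle_mean=1.0e9, ec50_um=1.0, emax_pct=90.0),
    doses_um=[0.3, 1.0, 3.0, 10.0],
    n_replicates=4,
    dispersion=0.1,
    seed=2,
)
counts = GroupedCounts.from_frame(study)
doses = {"vehicle": 0.0, "dose_0.3": 0.3, "dose_1": 1.0, "dose_3": 3.0, "dose_10": 10.0}
fit = ev_dose_response(counts, doses)
print(
    f"EV release EC50 = {fit.ic50_um:.2f} uM, inhibition reached in range = "
    f"{fit.efficacy:.0f}% (planted EC50 1.0 uM, Emax 90%)"
)

# in vivo: EV counts per arm, percent reduction and group comparison
invivo = simulate_ev_study(
    group_means={"saline": 2.0e8, "il1b": 1.0e9, "il1b_treated": 0.49e9},
    n_replicates=5,
    dispersion=0.15,
    seed=3,
)
groups = GroupedCounts.from_frame(invivo)
red = percent_reduction(groups, groups, "il1b_treated", "il1b")
print(f"EV reduction by treatment: {red.estimate_pct:.0f} +/- {red.se_pct:.0f}% (planted 51%)")
res = anova_tukey(groups)
print(f"one-way ANOVA: F = {res.f_statistic:.1f}, p = {res.p_value:.2g}")
print(res.tukey[["group_1", "group_2", "p_adj", "reject"]].to_string(index=False))

# liver cytokine induction, 2^-ddCt vs the saline group
qpcr = simulate_qpcr(
    {"il1b": {"tnfa": 4.0, "il6": 3.0}}, n=5, noise_sd=0.1, seed=4,
    control_group="saline",
)
print(ddct_fold_change(qpcr, "saline").to_string(index=False))
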