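"""Flag promiscuous preys across control screens by rank products.

Simulates 9 control-bait screens in which 5 preys are enriched in every
screen (frequent fliers), runs the rank-product permutation test and
reports which preys are flagged at adjusted p <= 0.05.
"""

from cftrscreen import (
    ControlScreenMatrix,
    ScreenSimConfig,
    flag_frequent_fliers,
    simulate_control_screens,
)

cfg = ScreenSimConfig(
    n_orfs=500, n_true_interactors=20, n_fliers=5, flier_fold=100.0, seed=17
)
cpm, truth = simulate_control_screens(cfg)
result = flag_frequent_fliers(
    ControlScreenMatrix.from_frame(cpm), n_iter=20_000, alpha=0.05, seed=18
)

flagged = result.fliers()
true_fliers = set(truth.loc[truth["role"] == "flier", "orf_id"])
print(f"flagged {len(flagged)} fliers: {sorted(flagged)}")
print(f"ground truth: {sorted(true_fliers)}")
top = result.table.nsmallest(8, "rank_product")
print(top.to_string(index=False))
print(
    "# A rank product near 1 means the prey had the highest CPM in nearly\n"
    "# every control screen - the signature of an assay artifact rather than\n"
    "# a bait-specific interactor. Permutation p-values of 0 mean no random\n"
    "# rank assignment produced a product that small in 20,000 iterations."
)
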