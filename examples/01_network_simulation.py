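"""Gene deletion vs duplication in a Wagner-type regulatory network.

Samples viable network sets (S(0), w, S_eq) of N = 10 genes at full
connectivity, perturbs each by deleting or duplicating k genes, relaxes the
perturbed network, and reports how often the new equilibrium is a *novel
stable state* (deletion: Hamming distance to the old equilibrium exceeds the
k positions forced to zero; duplication: any original gene changes state).
"""

from volvoloss.network import SimulationConfig, run_ensemble

config = SimulationConfig(
    n_genes=10,
    connectivity=1.0,
    k_values=(4, 5, 6),
    trials_per_k=300,
    seed=1,
)

print(f"{'mode':12s} {'k':>2s} {'novel/all':>9s} {'novel/converged':>15s}")
for mode in ("deletion", "duplication"):
    for res, extra in run_ensemble(config, mode, return_trials=True):
        conv = res.trials - res.n_nonconverged
        novel = int(extra["novel"].sum())
        print(
            f"{mode:12s} {res.k:2d} {res.proportion_novel_stable:9.3f} "
            f"{novel / conv:15.3f}"
        )

print(
    "\nAmong trials that reach a stable state, deletion changes the surviving"
    "\ngenes' expression more often than duplication changes the originals' —"
    "\nthe model's argument that gene loss can generate phenotypic novelty."
)
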