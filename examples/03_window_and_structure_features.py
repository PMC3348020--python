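"""Neighbouring and surrounding residues: richer encodings, better fits.

When the mutated residue alone under-explains the response, the protocol
adds (a) the local-sequence window -- the summed property of the 2k+1
wild-type residues around the site minus the mutant's value -- and (b) the
structural neighbourhood -- the property sum over residues within 8 A of the
site minus the mutant's value.  Here the planted signal lives in the window
encoding, so a mutation-only search underfits and the window search recovers
the full signal.
"""

from mutprop import (
    SimulationConfig,
    build_feature_matrix,
    default_property_table,
    exhaustive_subset_search,
    simulate_mutation_dataset,
)

table = default_property_table()
config = SimulationConfig(seed=21, n_mutants=24, noise_sd=0.05,
                          encoding="seq_window", k=2)
dataset, truth = simulate_mutation_dataset(table, config)
print(f"N = {dataset.n} mutants; signal encoding: window of k = {truth.k} "
      f"(length {2 * truth.k + 1})\n")

for encodings, label in (
    (["delta"], "mutation only        "),
    (["seq_window"], "sequence window      "),
    (["delta", "seq_window"], "mutation + window    "),
):
    fm = build_feature_matrix(table, dataset, encodings=encodings, k=2)
    rep = exhaustive_subset_search(fm, dataset.responses, sizes=[3], top_m=1)
    print(f"{label} best R = {rep.best.R:.3f}   "
          f"({rep.n_models} models over {rep.n_columns} columns)")

print("\nThe jump in R when window features enter mirrors the protocol's")
print("finding that neighbouring-residue information is often decisive;")
print("an analogous 'structural' encoding uses the 8 A contact neighbourhood")
print("of a CA-trace structure (see mutprop.features.structural_effect).")
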