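"""Stand-in differential-expression test with Benjamini-Hochberg correction.

Simulates a dataset in which a known fraction of entities carries a planted
baseline shift at each time-point, runs the Welch test of each time-point
against the controls, and reports how many entities are called DE at the
0.05 adjusted-p cut-off.
"""

from temponet.preprocess import de_table_for_dataset
from temponet.simulate import generate_scenario, simulate_expression

scenario = generate_scenario(15, 45, edge_density=0.0, seed=7, frac_de=0.4)
dataset = simulate_expression(scenario)
de = de_table_for_dataset(dataset, alpha=0.05)

for tp in scenario.timepoints:
    sub = de[de["timepoint"] == tp]
    n_mirna = int(sub[(sub["type"] == "miRNA") & sub["de"]].shape[0])
    n_mrna = int(sub[(sub["type"] == "mRNA") & sub["de"]].shape[0])
    print(f"{tp:>8}: {n_mirna:2d} DE miRNAs, {n_mrna:2d} DE mRNAs")

planted = sum(1 for (node, tp) in scenario.baseline)
called = int(de["de"].sum())
print(f"\nplanted shifts: {planted}; DE calls across the time-course: {called}")
print("With 3-vs-3 replicates and a 5-sigma planted shift, most planted "
      "entities are recovered while the BH correction keeps false calls rare.")
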