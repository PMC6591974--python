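"""Generate a synthetic benchmark with planted essential proteins, rank the
proteins, and measure how well the planted set is recovered.

The generator couples essentiality to all four evidence channels (hub degree,
domain families, compartment preference, conservation); the jackknife area is
0.5 for a random ranking and rises toward ~0.89 (its ceiling at this
essential fraction) as recovery improves.
"""

from rwhn import (
    SyntheticConfig,
    evaluate_ranking,
    generate_dataset,
    run_pipeline,
)

config = SyntheticConfig(n_proteins=300, seed=42)
dataset = generate_dataset(config)
print(f"dataset: {config.n_proteins} proteins, {len(dataset.interactions)} "
      f"interactions, {len(dataset.essentials)} planted essentials")

result = run_pipeline(
    dataset.interactions,
    dataset.domain_annotations,
    dataset.localization,
    dataset.orthology,
    alpha=0.3,  # restart probability
    beta=0.2,   # protein<->domain jump probability
)
print(f"walk converged after {result.walk.iterations} iterations")

report = evaluate_ranking(result.ranking, dataset.essentials)
print(f"normalized jackknife area: {report.jackknife_area:.3f}  (0.5 = chance)")
print("true essentials among top-ranked fractions:")
for frac, (candidates, hits) in sorted(report.top_counts.items()):
    print(f"  top {frac:>4.0%}: {hits:3d} / {candidates:3d} candidates "
          f"(precision {hits / candidates:.2f})")
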