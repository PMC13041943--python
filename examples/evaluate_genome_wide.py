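"""Genome-wide region-level evaluation of prophage predictions.

Runs the extraction pipeline over a five-genome synthetic benchmark and
scores the calls against the implanted truth on a 1 kb grid, macro-averaging
per-genome metrics — the same protocol used to compare detection tools.
"""

import prophagekit as pk

spec = pk.SimSpec(seed=7)
genomes, truth, tracks = pk.simulate_benchmark(spec)
lengths = {g.genome_id: g.length_nt for g in genomes}

predictions = []
for track in tracks:
    predictions.extend(pk.extract_prophages(track, pk.ExtractionConfig()))

per_genome, macro = pk.evaluate_genome_wide(
    predictions, truth, lengths, step=spec.step
)

print(f"{'genome':<10} {'TP':>4} {'FP':>4} {'FN':>4} {'MCC':>6} {'recall':>7}")
for e in per_genome:
    print(f"{e.genome_id:<10} {e.counts.tp:>4} {e.counts.fp:>4} "
          f"{e.counts.fn:>4} {e.mcc:>6.3f} {e.recall:>7.3f}")
print(f"\nmacro MCC {macro['mcc']:.3f}, recall {macro['recall']:.3f}, "
      f"FPR {macro['fpr']:.4f}")

# MCC near 1 and FPR near 0 mean the calls tile the implants almost exactly;
# recall is the macro-averaged fraction of truth segments recovered.
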