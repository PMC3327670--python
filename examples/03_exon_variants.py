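"""Detect exon inclusion/exclusion events between conditions.

Each expressed exon (>= 10 RPKM in one of the compared conditions) is
tested against the rest of its gene in a pooled 2x2 table: Fisher's
exact test (p < 0.05) plus a Bayesian sign-error rate (e <= 0.1), then
restricted to exons carrying a UCSC-knownAlt-style label.  Inclusion
means usage rose in the treated arm (TAC/exercise); exclusion means it
rose in the control arm.
"""

import cardiosplice as cs

fx = cs.simulate_study(seed=1, materialize_reads=False)
mapped = fx.samples.set_index("sample_id")["mapped_reads_total"]
rpkm_exon = cs.compute_rpkm(fx.exon_counts, fx.annotation.exon_lengths(),
                            mapped)
calls = cs.detect_exon_variants(fx.exon_counts, fx.gene_counts, rpkm_exon,
                                fx.annotation, fx.samples)
for name in cs.CONTRASTS:
    sub = calls[calls["contrast"] == name]
    inc = (sub["direction"] == "inclusion").sum()
    exc = (sub["direction"] == "exclusion").sum()
    print(f"{name}: {inc} inclusions, {exc} exclusions")

summary = cs.summarize_variant_types(calls)
pah = summary[summary["contrast"] == "PAH"]
print("\nPAH alternative-splicing type mix (fraction of calls):")
print(pah[["alt_type", "proportion"]].round(2).to_string(index=False))

spiked = fx.truth.exons[fx.truth.exons["is_as_event"]]
keyed = set(zip(calls["exon_id"], calls["contrast"]))
found = sum((e, c) in keyed for e, c in zip(spiked.exon_id, spiked.contrast))
print(f"\nplanted events recovered: {found}/{len(spiked)}")
# The type mix reflects the knownAlt labels of the called exons; with
# the default label weights, alternative promoters and cassette exons
# dominate, as they do in real hypertrophy data.
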