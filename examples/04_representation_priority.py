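"""Which taxa are under-represented in the library, and which families
should be sequenced first?"""

from pathlib import Path

from barcodegap import (
    RepresentationFlag,
    SyntheticConfig,
    TaxLevel,
    annotate_phylogeny,
    classify_representation,
    fit_cauchy,
    generate_bundle,
    load_accessions,
    load_checklist,
    priority_table,
    proportion_deltas,
    write_bundle,
)

paths = write_bundle(generate_bundle(SyntheticConfig(seed=1)), "example_inputs")
checklist = load_checklist(paths["checklist"])
accessions, _ = load_accessions(paths["accessions"], checklist)

deltas = proportion_deltas(checklist, accessions, TaxLevel.GENUS)
fit = fit_cauchy([d.delta for d in deltas])
flagged = classify_representation(deltas, fit)
under = [d for d in flagged if d.flag in
         (RepresentationFlag.UNDER, RepresentationFlag.STRONG_UNDER)]
print(f"Cauchy fit to genus deltas: location={fit.location:.5f} "
      f"scale={fit.scale:.5f}")
print(f"under-represented genera (outside the 90% band): "
      f"{[d.taxon for d in under]}")
# delta = flora share - barcode share; genera in the fitted distribution's
# upper tail hold more of the flora than of the library.

scores = priority_table(checklist, accessions)
print("\ntop sequencing priorities (P = unbarcoded + threatened-unbarcoded"
      " + endemic-unbarcoded fractions, 0-3):")
for s in scores[:5]:
    print(f"  {s.family:18s} P={s.P:.2f} "
          f"({s.p_nobarcode:.2f}+{s.p_threat:.2f}+{s.p_endemic:.2f})")

nwk, _, report = annotate_phylogeny(Path(paths["tree"]).read_text(), scores)
Path("example_inputs/priority_annotated.nwk").write_text(nwk + "\n")
print(f"\nannotated family tree written "
      f"({len(scores) - len(report.tips_missing_scores)} tips carry [&P=...])")
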