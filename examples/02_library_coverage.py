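"""Library completeness: taxon coverage, marker evenness and overlap."""

from barcodegap import (
    MarkerRegion,
    SyntheticConfig,
    TaxLevel,
    generate_bundle,
    load_accessions,
    load_checklist,
    marker_table,
    taxon_coverage,
    venn_overlap,
    write_bundle,
)

paths = write_bundle(generate_bundle(SyntheticConfig(seed=1)), "example_inputs")
checklist = load_checklist(paths["checklist"])
accessions, _ = load_accessions(paths["accessions"], checklist)

for level in (TaxLevel.SPECIES, TaxLevel.GENUS, TaxLevel.FAMILY):
    r = taxon_coverage(checklist, accessions, level)
    print(f"{level.value:8s}: {r.covered}/{r.total} covered ({r.percent}%)")
# A species is covered when >=1 sequence of any of the ten barcode
# regions exists; genus/family coverage asks whether any member species is.

print("\nper-marker summary (top five by sequences):")
rows = sorted(marker_table(checklist, accessions),
              key=lambda r: -r["n_sequences"])[:5]
for r in rows:
    print(f"  {r['marker']:10s} n={r['n_sequences']:5d} "
          f"species={r['n_species']:4d} ({r['species_pct']:.1f}%) "
          f"J_species={r['J_species']:.3f}")
# Pielou J near 1 means sequences are spread evenly across taxa; low J
# means effort is piled onto a few species.

v = venn_overlap(checklist, accessions, [MarkerRegion.RBCL, MarkerRegion.MATK])
print(f"\nrbcL+matK: {v.intersection} species hold both "
      f"({v.intersection_pct:.1f}% of the flora)")
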