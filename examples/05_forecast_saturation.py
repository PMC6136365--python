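"""How fast is the library growing, and when will every taxon have a
barcode?"""

from barcodegap import (
    SeriesKind,
    SyntheticConfig,
    bin_by_trimester,
    fit_exponential,
    fit_logistic_fixed_a,
    generate_bundle,
    load_accessions,
    load_checklist,
    parse_quarter,
    saturation_date,
    write_bundle,
)

paths = write_bundle(generate_bundle(SyntheticConfig(seed=1)), "example_inputs")
checklist = load_checklist(paths["checklist"])
accessions, _ = load_accessions(paths["accessions"], checklist)
t_start = parse_quarter("1995Q3")

series = bin_by_trimester(accessions, SeriesKind.SEQUENCES)
ef = fit_exponential(series, t_start)
print(f"sequences: N(t) = {ef.N0:.1f} exp({ef.r:.3f} t)  "
      f"(doubling every {ef.doubling_time_years:.2f} years)")
# t is measured in trimesters (calendar quarters).

totals = {SeriesKind.SPECIES: len({r.binomial for r in checklist}),
          SeriesKind.GENERA: len({r.genus for r in checklist}),
          SeriesKind.FAMILIES: len({r.family for r in checklist})}
for kind, total in totals.items():
    s = bin_by_trimester(accessions, kind, checklist)
    fit = fit_logistic_fixed_a(s, total, t_start)
    sat = saturation_date(fit)
    print(f"{kind.value:8s}: N(t) = {total}/(1 + {fit.c:.1f} exp({fit.b:.3f} t))"
          f" -> complete by {sat.year}")
# The asymptote is fixed at the known taxon total, so the logistic fit
# answers *when* the library saturates, not whether.
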