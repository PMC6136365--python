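"""Orchestration of the full gap analysis into one report bundle.

``run_full_report`` executes every stage on the loaded inputs and writes:

* table1.csv          coverage by source and taxonomic level
* table2.csv          per-marker sequence/species counts and Pielou J
* venn.json           2/3-marker species overlaps for the core combinations
* survey_coverage.csv per-survey abundance-weighted coverage per level
* survey_summary.json descriptive statistics + bootstrap CI of the mean
* representation.csv  family- and genus-level deltas with flags
* priority.csv        family priority scores (and annotated tree if given)
* accumulation.json   growth fits and projected saturation years
* regression.json     NB regression, LRTs and the core-barcode contrast
* run.log             config hash, seed, row counts, stage outcomes

Stages are independent: a failing stage is logged and later stages still
run.  Every number in the bundle is reproducible from the inputs plus the
seed recorded in the log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import coverage as cov
from . import representation as rep
from .accumulation import (
    SeriesKind,
    bin_by_trimester,
    fit_exponential,
    fit_logistic_fixed_a,
    parse_quarter,
    saturation_date,
)
from .io import load_accessions, load_checklist, load_surveys, load_synonyms
from .markers import ALL_MARKERS, MarkerRegion
from .records import Source, TaxLevel
from .regression import core_barcode_share_test, run_nb_analysis

log = logging.getLogger("barcodegap")


@dataclass
class RunConfig:
    checklist: Path
    accessions: Path
    out_dir: Path
    surveys: Optional[Path] = None
    tree: Optional[Path] = None
    synonyms: Optional[Path] = None
    markers: Sequence[MarkerRegion] = ALL_MARKERS
    t_start: str = "1995Q3"
    bootstrap_reps: int = 10_000
    seed: int = 20180101

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        kwargs = {}
        for key in ("checklist", "accessions", "out_dir", "surveys", "tree", "synonyms"):
            if raw.get(key):
                kwargs[key] = base / raw[key] if not Path(raw[key]).is_absolute() \
                    else Path(raw[key])
        for key in ("t_start", "bootstrap_reps", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "markers" in raw:
            from .markers import parse_marker_set
            kwargs["markers"] = parse_marker_set(str(raw["markers"]))
        return cls(**kwargs)

    def digest(self) -> str:
        payload = {
            k: str(v) for k, v in dataclasses.asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


_VENN_COMBOS = [
    (MarkerRegion.RBCL, MarkerRegion.MATK),
    (MarkerRegion.RBCL, MarkerRegion.ITS),
    (MarkerRegion.RBCL, MarkerRegion.PSBA_TRNH),
    (MarkerRegion.MATK, MarkerRegion.PSBA_TRNH),
    (MarkerRegion.RBCL, MarkerRegion.MATK, MarkerRegion.ITS),
    (MarkerRegion.RBCL, MarkerRegion.MATK, MarkerRegion.PSBA_TRNH),
]


def run_full_report(config: RunConfig) -> dict:
    """Run every stage; returns {artifact name: path or error string}."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict[str, str] = {}
    log.info("config digest %s seed %d", config.digest(), config.seed)

    try:
        checklist = load_checklist(config.checklist)
        synonyms = load_synonyms(config.synonyms) if config.synonyms else None
        accessions, report = load_accessions(config.accessions, checklist, synonyms)
        log.info(
            "loaded %d species; %d accession rows (%d resolved, %d unresolved,"
            " %d skipped, %d infraspecific folded)",
            len(checklist), report.n_rows, report.n_resolved,
            report.n_unresolved, report.n_skipped, report.n_trinomial,
        )
    except Exception:
        log.exception("input loading failed; nothing to do")
        log.removeHandler(handler)
        raise

    def stage(name: str, fn) -> None:
        try:
            path = fn()
            results[name] = str(path)
            log.info("stage %s -> %s", name, path)
        except Exception as exc:
            results[name] = f"ERROR: {exc}"
            log.exception("stage %s failed", name)

    # ---- table 1: coverage by source and level -------------------------
    def _table1():
        rows = []
        groups = {
            "genbank": [a for a in accessions if a.source is Source.GENBANK],
            "local_study": [a for a in accessions if a.source is Source.LOCAL_STUDY],
            "total": accessions,
        }
        for src, accs in groups.items():
            row = {"source": src,
                   "n_accessions": sum(1 for a in accs if a.resolved and a.is_barcode)}
            for level in (TaxLevel.FAMILY, TaxLevel.GENUS, TaxLevel.SPECIES):
                r = cov.taxon_coverage(checklist, accs, level, config.markers)
                row[f"n_{level.value}"] = r.covered
                row[f"pct_{level.value}"] = r.percent
            rows.append(row)
        path = out / "table1.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    stage("table1", _table1)

    # ---- table 2: per-marker counts + evenness -------------------------
    def _table2():
        df = pd.DataFrame(cov.marker_table(checklist, accessions))
        df["species_pct"] = df["species_pct"].round(1)
        for c in ("J_family", "J_genus", "J_species"):
            df[c] = df[c].round(3)
        path = out / "table2.csv"
        df.to_csv(path, index=False)
        return path

    stage("table2", _table2)

    # ---- venn overlaps -------------------------------------------------
    def _venn():
        payload = []
        for combo in _VENN_COMBOS:
            v = cov.venn_overlap(checklist, accessions, combo)
            payload.append({
                "markers": [m.value for m in v.markers],
                "regions": {
                    "&".join(m.value for m, inc in zip(v.markers, pat) if inc):
                        n for pat, n in v.regions.items()
                },
                "union": v.union,
                "intersection": v.intersection,
                "intersection_pct": round(v.intersection_pct, 1),
            })
        path = out / "venn.json"
        path.write_text(json.dumps(payload, indent=2))
        return path

    stage("venn", _venn)

    # ---- survey coverage -----------------------------------------------
    if config.surveys and Path(config.surveys).exists():
        def _surveys():
            surveys = load_surveys(config.surveys, checklist)
            log.info("loaded %d surveys, %d individuals", len(surveys),
                     sum(s.total_individuals for s in surveys))
            rows = []
            summaries = {}
            for level in (TaxLevel.SPECIES, TaxLevel.GENUS, TaxLevel.FAMILY):
                covs = [cov.survey_coverage(s, checklist, accessions, level,
                                            config.markers)
                        for s in surveys]
                for c in covs:
                    rows.append({
                        "survey_id": c.survey_id, "level": level.value,
                        "proportion_covered": round(c.proportion_covered, 4),
                        "proportion_unidentified": round(c.proportion_unidentified, 4),
                    })
                s = cov.aggregate_survey_coverage(
                    covs, n_boot=config.bootstrap_reps, seed=config.seed)
                summaries[level.value] = {
                    "mean_pct": round(100 * s.mean, 1),
                    "median_pct": round(100 * s.median, 1),
                    "ci95_pct": [round(100 * s.ci_low, 1), round(100 * s.ci_high, 1)],
                    "range_pct": [round(100 * s.min, 1), round(100 * s.max, 1)],
                    "n_surveys": s.n_surveys,
                }
            pd.DataFrame(rows).to_csv(out / "survey_coverage.csv", index=False)
            (out / "survey_summary.json").write_text(json.dumps(summaries, indent=2))
            return out / "survey_summary.json"

        stage("survey_coverage", _surveys)
    else:
        results["survey_coverage"] = "SKIPPED: no surveys file"
        log.warning("surveys file missing; survey stage skipped")

    # ---- representation deltas -----------------------------------------
    def _representation():
        frames = []
        for level in (TaxLevel.FAMILY, TaxLevel.GENUS):
            deltas = rep.proportion_deltas(checklist, accessions, level,
                                           config.markers)
            fit = rep.fit_cauchy([d.delta for d in deltas])
            flagged = rep.classify_representation(deltas, fit)
            frames.append(pd.DataFrame([
                {"level": level.value, "taxon": d.taxon,
                 "delta": round(d.delta, 6), "flag": d.flag.value}
                for d in flagged
            ]))
            log.info("%s-level Cauchy fit: location %.5f scale %.5f",
                     level.value, fit.location, fit.scale)
        path = out / "representation.csv"
        pd.concat(frames).to_csv(path, index=False)
        return path

    stage("representation", _representation)

    # ---- priority scores + tree ----------------------------------------
    def _priority():
        scores = rep.priority_table(checklist, accessions, config.markers)
        pd.DataFrame([
            {"family": s.family, "p_nobarcode": round(s.p_nobarcode, 4),
             "p_threat": round(s.p_threat, 4), "p_endemic": round(s.p_endemic, 4),
             "P": round(s.P, 4)}
            for s in scores
        ]).to_csv(out / "priority.csv", index=False)
        if config.tree and Path(config.tree).exists():
            nwk, _, recon = rep.annotate_phylogeny(
                Path(config.tree).read_text(), scores)
            (out / "priority_annotated.nwk").write_text(nwk + "\n")
            if recon.families_missing_from_tree or recon.tips_missing_scores:
                log.warning("tree reconciliation: %d families missing from tree,"
                            " %d tips without scores",
                            len(recon.families_missing_from_tree),
                            len(recon.tips_missing_scores))
        return out / "priority.csv"

    stage("priority", _priority)

    # ---- accumulation fits ---------------------------------------------
    def _accumulation():
        t_start = parse_quarter(config.t_start)
        totals = {
            SeriesKind.SPECIES: len({r.binomial for r in checklist}),
            SeriesKind.GENERA: len({r.genus for r in checklist}),
            SeriesKind.FAMILIES: len({r.family for r in checklist}),
        }
        seq_series = bin_by_trimester(accessions, SeriesKind.SEQUENCES)
        ef = fit_exponential(seq_series, t_start)
        payload = {
            "sequences_exponential": {
                "N0": round(ef.N0, 2), "r_per_trimester": round(ef.r, 5),
                "doubling_time_years": round(ef.doubling_time_years, 2),
                "rss": ef.rss,
            }
        }
        for kind, total in totals.items():
            series = bin_by_trimester(accessions, kind, checklist)
            lf = fit_logistic_fixed_a(series, total, t_start)
            sat = saturation_date(lf)
            payload[kind.value] = {
                "a": total, "b": round(lf.b, 5), "c": round(lf.c, 3),
                "rss": lf.rss, "saturation_year": sat.year,
                "saturation_quarter": sat.quarter,
            }
        path = out / "accumulation.json"
        path.write_text(json.dumps(payload, indent=2))
        return path

    stage("accumulation", _accumulation)

    # ---- endemism regression -------------------------------------------
    def _regression():
        full, lrt = run_nb_analysis(checklist, accessions, config.markers)
        share = core_barcode_share_test(checklist, accessions)
        payload = {
            "nb_regression": {
                "coefficients": {k: round(v, 4) for k, v in full.coefficients.items()},
                "dispersion_theta": round(full.dispersion, 4),
                "fitted_means": {k: round(v, 4) for k, v in full.fitted_means.items()},
                "loglik": round(full.loglik, 2),
                "lrt": {"statistic": round(lrt.statistic, 2),
                        "df_model": lrt.df_model,
                        "df_residual": lrt.df_residual,
                        "p_value": lrt.p_value},
            },
            "core_barcode_share": {
                "share_endemic_pct": round(100 * share.share_endemic, 1),
                "share_other_pct": round(100 * share.share_other, 1),
                "lrt_statistic": round(share.lrt.statistic, 2),
                "p_value": share.lrt.p_value,
            },
        }
        path = out / "regression.json"
        path.write_text(json.dumps(payload, indent=2))
        return path

    stage("regression", _regression)

    log.info("run complete: %s", {k: v.split("/")[-1] for k, v in results.items()})
    log.removeHandler(handler)
    handler.close()
    return results
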