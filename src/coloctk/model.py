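"""Colocalization model: a query interval set tested against a curated
profile collection.

`Colocalization` is built from data (parsed query intervals + a profile
collection); `fit()` runs the full pipeline — preprocessing, tissue and
category filtering, optional outlier removal per replicate group, the
Fisher/odds-ratio/combo enrichment test per retained profile, group-median
aggregation and tissue summaries — and returns a `ColocalizationResults`
carrying the prioritization table, per-group medians, summaries and a
`summary()` text report.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats
from .curation import (
    Profile,
    ProfileGroup,
    TissueHierarchy,
    group_profiles,
    load_manifest,
    load_tissue_hierarchy,
    remove_outliers,
)
from .intervals import (
    GenomicInterval,
    QueryOptions,
    build_index,
    count_overlaps,
    parse_bed,
    parse_vcf,
    preprocess_query,
)

__all__ = ["Colocalization", "ColocalizationResults", "calibrate_cutoffs", "CalibrationReport"]

PROFILE_TABLE_COLUMNS = [
    "rank",
    "profile_id",
    "group_id",
    "tissue",
    "sub_tissue",
    "cell_type",
    "target",
    "category",
    "overlaps",
    "query_hits",
    "p_value",
    "odds_ratio",
    "combo_score",
    "classification",
    "group_median_combo",
    "best_in_group",
]


class Colocalization:
    """Enrichment/depletion of query genomic intervals against a profile collection.

    Parameters
    ----------
    query:
        Parsed query intervals (before preprocessing).
    profiles:
        Validated profile metadata records.
    hierarchy:
        Tissue hierarchy used for filtering and summary roll-up.
    options:
        Query preprocessing options and tissue/category filters.
    curate:
        Apply outlier-profile removal per replicate group (default True).
    enrich_cutoff, deplete_cutoff:
        Combo-score classification cutoffs.
    profile_intervals:
        Optional pre-loaded intervals per profile_id (skips file reads).
    """

    def __init__(
        self,
        query: Sequence[GenomicInterval],
        profiles: Sequence[Profile],
        hierarchy: TissueHierarchy,
        options: QueryOptions | None = None,
        curate: bool = True,
        enrich_cutoff: float = stats.ENRICH_CUTOFF,
        deplete_cutoff: float = stats.DEPLETE_CUTOFF,
        profile_intervals: dict[str, list[GenomicInterval]] | None = None,
    ):
        self.query = list(query)
        self.profiles = list(profiles)
        self.hierarchy = hierarchy
        self.options = options or QueryOptions()
        self.curate = curate
        self.enrich_cutoff = enrich_cutoff
        self.deplete_cutoff = deplete_cutoff
        self._profile_intervals = profile_intervals

    @classmethod
    def from_files(
        cls,
        query_path,
        manifest_path,
        hierarchy_path,
        query_format: str = "bed",
        **kwargs,
    ) -> "Colocalization":
        """Build a model from a BED/VCF query, a manifest TSV and a hierarchy YAML."""
        if query_format == "bed":
            query, _ = parse_bed(query_path)
        elif query_format == "vcf":
            query, _ = parse_vcf(query_path)
        else:
            raise ValueError(f"query_format must be 'bed' or 'vcf', got {query_format!r}")
        hierarchy = load_tissue_hierarchy(hierarchy_path)
        profiles = load_manifest(manifest_path, hierarchy=hierarchy)
        return cls(query, profiles, hierarchy, **kwargs)

    def _filtered_profiles(self) -> list[Profile]:
        selected = self.profiles
        if self.options.tissues is not None:
            expanded = self.hierarchy.expand(sorted(self.options.tissues))
            selected = [
                p for p in selected
                if p.tissue in expanded or (p.sub_tissue and p.sub_tissue in expanded)
            ]
        if self.options.categories is not None:
            selected = [p for p in selected if p.category in self.options.categories]
        if not selected:
            raise ValueError("zero profiles remain after tissue/category filtering")
        return selected

    def _intervals_for(self, profile: Profile) -> list[GenomicInterval]:
        if self._profile_intervals is not None:
            return self._profile_intervals[profile.profile_id]
        return profile.load_intervals()

    def fit(self) -> "ColocalizationResults":
        """Run the colocalization pipeline; fully deterministic for fixed inputs."""
        query, report = preprocess_query(self.query, self.options)
        if not query:
            raise ValueError("zero query intervals remain after preprocessing")

        selected = self._filtered_profiles()
        groups = group_profiles(selected)
        if self.curate:
            ivs_cache = {p.profile_id: self._intervals_for(p) for p in selected}
            groups = [
                remove_outliers(
                    g,
                    self.options.genome_size,
                    intervals=[ivs_cache[p.profile_id] for p in g.members],
                )
                for g in groups
            ]
        else:
            ivs_cache = None

        q_total_len = sum(iv.length for iv in query)
        results: list[stats.EnrichmentResult] = []
        for g in groups:
            for p in g.retained:
                ivs = ivs_cache[p.profile_id] if ivs_cache else self._intervals_for(p)
                results.append(self._test_profile(p, g.group_id, query, q_total_len, ivs))

        group_results = {}
        for g in groups:
            members = [r for r in results if r.group_id == g.group_id]
            if members:
                group_results[g.group_id] = stats.aggregate_group_median(
                    members, self.enrich_cutoff, self.deplete_cutoff
                )

        results.sort(key=lambda r: (-r.combo_score, r.p_value, r.profile_id))
        return ColocalizationResults(self, results, group_results, groups, report)

    def _test_profile(
        self, profile: Profile, group_id: str, query, q_total_len: int, ivs
    ) -> stats.EnrichmentResult:
        index = build_index(ivs)
        overlap = count_overlaps(query, index)
        mean_size = stats.mean_interval_size(
            len(query), q_total_len, index.count, index.total_length
        ) if (len(query) + index.count) else 1.0
        table = stats.build_contingency(
            len(query), index.count, overlap.pairs, self.options.genome_size, mean_size
        )
        p = stats.fisher_exact_two_tailed(table)
        orv = stats.odds_ratio(table)
        combo = stats.combo_score(p, orv)
        return stats.EnrichmentResult(
            profile_id=profile.profile_id,
            overlaps=overlap.pairs,
            query_hits=overlap.query_hits,
            p_value=p,
            odds_ratio=orv,
            combo_score=combo,
            classification=stats.classify_enrichment(
                combo, self.enrich_cutoff, self.deplete_cutoff
            ),
            table=table,
            group_id=group_id,
            tissue=profile.tissue,
            sub_tissue=profile.sub_tissue,
            cell_type=profile.cell_type,
            target=profile.target,
            category=profile.category,
        )

    def config_hash(self) -> str:
        """Content hash identifying this job's configuration."""
        payload = json.dumps(
            {
                "options": self.options.to_dict(),
                "curate": self.curate,
                "cutoffs": [self.enrich_cutoff, self.deplete_cutoff],
                "query": [(iv.chrom, iv.start, iv.end) for iv in self.query],
                "profiles": sorted(p.profile_id for p in self.profiles),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class ColocalizationResults:
    """Fitted colocalization results: ranked profile statistics, group medians
    and tissue summaries."""

    def __init__(self, model, results, group_results, groups, preprocess_report):
        self.model = model
        self.results = results
        self.group_results = group_results
        self.groups = groups
        self.preprocess_report = preprocess_report

    @property
    def profile_table(self) -> pd.DataFrame:
        """Ranked prioritization table (combo desc, p asc, profile_id)."""
        rows = []
        for rank, r in enumerate(self.results, start=1):
            g = self.group_results.get(r.group_id)
            rows.append(
                {
                    "rank": rank,
                    "profile_id": r.profile_id,
                    "group_id": r.group_id,
                    "tissue": r.tissue,
                    "sub_tissue": r.sub_tissue or "",
                    "cell_type": r.cell_type or "",
                    "target": r.target,
                    "category": r.category,
                    "overlaps": r.overlaps,
                    "query_hits": r.query_hits,
                    "p_value": r.p_value,
                    "odds_ratio": r.odds_ratio,
                    "combo_score": r.combo_score,
                    "classification": r.classification,
                    "group_median_combo": g.median_combo if g else float("nan"),
                    "best_in_group": bool(g and g.best_profile_id == r.profile_id),
                }
            )
        return pd.DataFrame(rows, columns=PROFILE_TABLE_COLUMNS)

    @property
    def group_table(self) -> pd.DataFrame:
        rows = [
            {
                "group_id": g.group_id,
                "n_members": g.n_members,
                "median_combo": g.median_combo,
                "best_profile_id": g.best_profile_id,
                "classification": g.classification,
            }
            for g in sorted(
                self.group_results.values(), key=lambda g: (-g.median_combo, g.group_id)
            )
        ]
        return pd.DataFrame(
            rows, columns=["group_id", "n_members", "median_combo", "best_profile_id",
                           "classification"]
        )

    def tissue_summary(self) -> pd.DataFrame:
        """Per-tissue enriched/depleted/neutral counts, both cutoff-based and
        combo-sign-based; sub-tissue results roll up to their parent tissue
        and are reported at both levels."""
        return summarize_by_tissue(self.results, self.model.hierarchy)

    def summary(self) -> str:
        """Human-readable report of the fit."""
        df = self.profile_table
        n = len(df)
        counts = df["classification"].value_counts()
        buf = io.StringIO()
        buf.write("Colocalization results\n")
        buf.write("=" * 70 + "\n")
        buf.write(f"Query intervals (after preprocessing): {self.preprocess_report.n_output}")
        buf.write(f"  (removed by length filter: {self.preprocess_report.n_removed_length})\n")
        buf.write(f"Profiles evaluated: {n}   groups: {len(self.group_results)}\n")
        buf.write(
            f"Enriched: {counts.get('enriched', 0)}   "
            f"Depleted: {counts.get('depleted', 0)}   "
            f"Neutral: {counts.get('neutral', 0)}\n"
        )
        buf.write(
            f"Cutoffs: combo >= {self.model.enrich_cutoff} (enriched), "
            f"combo <= {self.model.deplete_cutoff} (depleted)\n"
        )
        buf.write("-" * 70 + "\n")
        top = df.head(10)[
            ["rank", "profile_id", "tissue", "target", "overlaps", "p_value",
             "odds_ratio", "combo_score", "classification"]
        ]
        buf.write(top.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
        buf.write("\n")
        return buf.getvalue()

    def save(self, outdir) -> dict[str, Path]:
        """Write the prioritization CSV, tissue summary CSV, group CSV and a
        machine-readable JSON of the full result."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "profiles": outdir / "prioritization.csv",
            "groups": outdir / "groups.csv",
            "tissues": outdir / "tissue_summary.csv",
            "json": outdir / "results.json",
        }
        self.profile_table.to_csv(paths["profiles"], index=False, float_format="%.10g")
        self.group_table.to_csv(paths["groups"], index=False, float_format="%.10g")
        self.tissue_summary().to_csv(paths["tissues"], index=False)
        payload = {
            "config_hash": self.model.config_hash(),
            "options": self.model.options.to_dict(),
            "preprocess": self.preprocess_report.__dict__,
            "profiles": self.profile_table.to_dict(orient="records"),
            "groups": self.group_table.to_dict(orient="records"),
        }
        paths["json"].write_text(json.dumps(payload, indent=1, default=str))
        return paths


def summarize_by_tissue(
    results: Sequence[stats.EnrichmentResult], hierarchy: TissueHierarchy
) -> pd.DataFrame:
    """Count enriched/depleted/neutral profiles per tissue and sub-tissue.

    Cutoff-based counts use each result's classification; sign-based counts
    (``n_positive``/``n_negative``) use the combo-score sign.  A result in a
    sub-tissue is counted under both the sub-tissue and its parent tissue.
    """
    rows: dict[str, dict] = {}

    def bump(tid: str, level: str, r: stats.EnrichmentResult) -> None:
        row = rows.setdefault(
            tid,
            {
                "tissue_id": tid, "level": level,
                "n_enriched": 0, "n_depleted": 0, "n_neutral": 0,
                "n_positive": 0, "n_negative": 0, "n_total": 0,
            },
        )
        row[f"n_{r.classification}"] += 1
        if r.combo_score > 0:
            row["n_positive"] += 1
        elif r.combo_score < 0:
            row["n_negative"] += 1
        row["n_total"] += 1

    for r in results:
        tid = r.sub_tissue or r.tissue
        if tid and tid in hierarchy:
            parent = hierarchy.parent_of(tid)
            if parent is None:
                bump(tid, "tissue", r)
            else:
                bump(tid, "sub_tissue", r)
                bump(parent, "tissue", r)
        elif r.tissue:
            bump(r.tissue, "tissue", r)

    df = pd.DataFrame(
        sorted(rows.values(), key=lambda d: (d["level"], d["tissue_id"])),
        columns=["tissue_id", "level", "n_enriched", "n_depleted", "n_neutral",
                 "n_positive", "n_negative", "n_total"],
    )
    return df


@dataclass
class CalibrationReport:
    """Null distribution of combo scores from random query sets.

    ``quantiles`` summarizes combo scores among results with p <= 0.05;
    ``exceedance`` maps candidate cutoffs to the fraction of all profile
    results whose combo meets/exceeds (enrichment, positive cutoffs) or
    falls below (depletion, negative cutoffs) the cutoff.
    """

    n_queries: int
    n_results: int
    n_significant: int
    quantiles: dict[float, float]
    exceedance: dict[float, float]
    combos: np.ndarray


def calibrate_cutoffs(
    profiles: Sequence[Profile],
    hierarchy: TissueHierarchy,
    n_queries: int,
    query_size: int,
    interval_length: int,
    genome_size: int,
    chromosomes: Sequence[tuple[str, int]],
    seed: int,
    options: QueryOptions | None = None,
    profile_intervals: dict[str, list[GenomicInterval]] | None = None,
    candidate_cutoffs: Sequence[float] = (2.0, 5.0, 10.0, -2.0, -5.0),
) -> CalibrationReport:
    """Monte-Carlo null calibration of combo-score cutoffs.

    Generates ``n_queries`` query sets of uniformly placed intervals, runs
    each against the collection (no curation: every profile evaluated), and
    reports the quantiles of combo scores among results with p <= 0.05 plus
    the fraction of all results beyond each candidate cutoff.
    """
    if n_queries <= 0:
        raise ValueError("n_queries must be positive")
    if not profiles:
        raise ValueError("profile collection is empty")
    from .synthetic import FixtureSpec, _random_intervals, _rng

    opts = options or QueryOptions(genome_size=genome_size)
    spec = FixtureSpec(
        genome_size=genome_size,
        chromosomes=tuple(chromosomes),
        interval_length=interval_length,
        planted_target=None,
        seed=seed,
    )
    combos: list[float] = []
    pvals: list[float] = []
    for q in range(n_queries):
        rng = _rng(spec, q)
        query = _random_intervals(spec, rng, query_size)
        m = Colocalization(
            query, profiles, hierarchy, options=opts, curate=False,
            profile_intervals=profile_intervals,
        )
        for r in m.fit().results:
            combos.append(r.combo_score)
            pvals.append(r.p_value)
    combos_arr = np.asarray(combos)
    pvals_arr = np.asarray(pvals)
    sig = combos_arr[pvals_arr <= 0.05]
    qlevels = (0.5, 0.9, 0.95, 0.99)
    quantiles = {
        q: (float(np.quantile(sig, q)) if sig.size else float("nan")) for q in qlevels
    }
    exceedance = {}
    for cut in candidate_cutoffs:
        if cut >= 0:
            exceedance[cut] = float(np.mean(combos_arr >= cut))
        else:
            exceedance[cut] = float(np.mean(combos_arr <= cut))
    return CalibrationReport(
        n_queries=n_queries,
        n_results=combos_arr.size,
        n_significant=int(sig.size),
        quantiles=quantiles,
        exceedance=exceedance,
        combos=combos_arr,
    )
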