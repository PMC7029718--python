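"""Deterministic synthetic fixtures: genomes, profile collections with
replicate groups and planted outliers, and query sets with planted
enrichment.

The generator emulates a desk-scale epigenomic profile collection: each
profile is a BED file of uniformly placed intervals on a small multi-
chromosome genome; replicate groups are jittered copies of a master
interval set (plus independent random "outlier" profiles); queries can be
planted inside a target profile's intervals at a configurable fraction to
create true enrichment.  A single seed drives counter-based per-profile
substreams so adding profiles never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .intervals import GenomicInterval, write_bed
from .curation import Profile, TissueHierarchy, load_tissue_hierarchy

__all__ = ["FixtureSpec", "SyntheticCollection", "make_profile_collection", "make_query"]

_TISSUE_LAYOUT = {
    "blood": ["monocyte", "lymphocyte"],
    "liver": ["hepatocyte"],
    "brain": ["cortex", "cerebellum"],
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic collection + query.

    Defaults describe the standard desk-scale scenario: a 10 Mb genome over
    two chromosomes, 20 profiles of 200 x 1 kb intervals (2% genomic
    coverage each), a query of 100 x 200 bp intervals with 80% planted
    inside the target profile, and replicate groups of 8 jittered copies
    (+/-100 bp) plus 3 independent random outliers.
    """

    genome_size: int = 10_000_000
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 6_000_000), ("chr2", 4_000_000))
    n_profiles: int = 20
    intervals_per_profile: int = 200
    interval_length: int | tuple[int, int] = 1_000
    planted_target: str | None = "profile_000"
    query_size: int = 100
    query_interval_length: int = 200
    fraction_inside: float = 0.8
    jitter: int = 100
    replicates: int = 0
    n_outliers: int = 0
    seed: int = 42

    def __post_init__(self) -> None:
        if sum(ln for _, ln in self.chromosomes) != self.genome_size:
            raise ValueError("chromosome lengths must sum to genome_size")
        if not (0 <= self.fraction_inside <= 1):
            raise ValueError("fraction_inside must be in [0, 1]")
        for name in ("n_profiles", "intervals_per_profile", "query_size", "jitter",
                     "replicates", "n_outliers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SyntheticCollection:
    """A generated collection: profiles, their intervals, manifest and hierarchy."""

    spec: FixtureSpec
    profiles: list[Profile]
    intervals: dict[str, list[GenomicInterval]]
    manifest_path: Path | None = None
    hierarchy_path: Path | None = None
    hierarchy: TissueHierarchy | None = None


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(np.random.SeedSequence((spec.seed, stream))))


def _draw_length(spec: FixtureSpec, rng: np.random.Generator) -> int:
    if isinstance(spec.interval_length, tuple):
        lo, hi = spec.interval_length
        return int(rng.integers(lo, hi + 1))
    return int(spec.interval_length)


def _random_intervals(
    spec: FixtureSpec, rng: np.random.Generator, n: int
) -> list[GenomicInterval]:
    """Place ``n`` intervals uniformly on the genome (overlaps are legal)."""
    chrom_names = [c for c, _ in spec.chromosomes]
    chrom_lens = np.array([ln for _, ln in spec.chromosomes], dtype=float)
    probs = chrom_lens / chrom_lens.sum()
    out: list[GenomicInterval] = []
    for _ in range(n):
        length = _draw_length(spec, rng)
        for _attempt in range(1000):
            ci = int(rng.choice(len(chrom_names), p=probs))
            limit = int(chrom_lens[ci]) - length
            if limit >= 0:
                start = int(rng.integers(0, limit + 1))
                out.append(GenomicInterval(chrom_names[ci], start, start + length))
                break
        else:
            raise ValueError(
                f"genome too small to place an interval of length {length}"
            )
    return out


def _jittered_copy(
    master: list[GenomicInterval],
    rng: np.random.Generator,
    jitter: int,
    chrom_len: dict[str, int],
) -> list[GenomicInterval]:
    out = []
    for iv in master:
        shift = int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0
        start = iv.start + shift
        start = max(0, min(start, chrom_len[iv.chrom] - iv.length))
        out.append(GenomicInterval(iv.chrom, start, start + iv.length))
    return out


def make_profile_collection(spec: FixtureSpec, outdir=None) -> SyntheticCollection:
    """Generate a self-consistent profile collection.

    ``spec.n_profiles`` singleton profiles (one group each, distinct
    targets) of uniform random intervals are always produced; if
    ``spec.replicates > 0`` an additional replicate group is appended with
    ``replicates`` jittered copies of a master set plus ``n_outliers``
    independent random profiles, all sharing (source, assay, tissue,
    target).  If ``outdir`` is given, BED files, the manifest TSV and the
    tissue-hierarchy YAML are written there; generation is byte-reproducible
    from the seed.
    """
    chrom_len = dict(spec.chromosomes)
    tissues = list(_TISSUE_LAYOUT.items())
    profiles: list[Profile] = []
    intervals: dict[str, list[GenomicInterval]] = {}

    def add_profile(pid: str, ivs, tissue: str, sub: str, target: str, cell: str) -> None:
        profiles.append(
            Profile(
                profile_id=pid,
                source="synthetic",
                assay_type="ChIP-seq",
                category="transcriptional_regulator",
                tissue=tissue,
                sub_tissue=sub,
                cell_type=cell,
                target=target,
                path=f"{pid}.bed",
            )
        )
        intervals[pid] = ivs

    for i in range(spec.n_profiles):
        rng = _rng(spec, i)
        tissue, subs = tissues[i % len(tissues)]
        sub = subs[i % len(subs)]
        add_profile(
            f"profile_{i:03d}",
            _random_intervals(spec, rng, spec.intervals_per_profile),
            tissue,
            sub,
            target=f"TF{i:03d}",
            cell=f"cell_{sub}",
        )

    if spec.replicates > 0:
        master_rng = _rng(spec, 10_000)
        master = _random_intervals(spec, master_rng, spec.intervals_per_profile)
        for r in range(spec.replicates):
            rng = _rng(spec, 10_001 + r)
            add_profile(
                f"rep_{r:03d}",
                _jittered_copy(master, rng, spec.jitter, chrom_len),
                "blood",
                "monocyte",
                target="TF_GROUP",
                cell="cell_group",
            )
        for k in range(spec.n_outliers):
            rng = _rng(spec, 20_000 + k)
            add_profile(
                f"outlier_{k:03d}",
                _random_intervals(spec, rng, spec.intervals_per_profile),
                "blood",
                "monocyte",
                target="TF_GROUP",
                cell="cell_group",
            )

    hierarchy = load_tissue_hierarchy(dict(_TISSUE_LAYOUT))
    coll = SyntheticCollection(spec, profiles, intervals, hierarchy=hierarchy)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for p in profiles:
            write_bed(intervals[p.profile_id], outdir / p.path)
        manifest = outdir / "manifest.tsv"
        header = "profile_id\tsource\tassay_type\tcategory\ttissue\tsub_tissue\tcell_type\ttarget\tpath"
        rows = [
            "\t".join(
                [p.profile_id, p.source, p.assay_type, p.category, p.tissue,
                 p.sub_tissue or "", p.cell_type or "", p.target, p.path]
            )
            for p in profiles
        ]
        manifest.write_text("\n".join([header, *rows]) + "\n")
        hier = outdir / "tissues.yaml"
        hier.write_text(yaml.safe_dump({t: list(s) for t, s in _TISSUE_LAYOUT.items()}))
        coll.manifest_path = manifest
        coll.hierarchy_path = hier
        coll.profiles = [
            Profile(**{**p.__dict__, "path": str(outdir / p.path)}) for p in profiles
        ]
    return coll


def make_query(
    spec: FixtureSpec, collection: SyntheticCollection, stream: int = 0
) -> list[GenomicInterval]:
    """Generate a query set with planted enrichment.

    ``round(fraction_inside * query_size)`` intervals are placed uniformly
    inside the planted target profile's intervals; the remainder uniformly
    in the genome.  Query intervals have fixed length
    ``spec.query_interval_length`` (at most the default maximum length, so
    preprocessing drops nothing).  ``stream`` decouples repeated draws.
    """
    rng = _rng(spec, 30_000 + stream)
    n_inside = round(spec.fraction_inside * spec.query_size)
    n_outside = spec.query_size - n_inside
    qlen = spec.query_interval_length
    out: list[GenomicInterval] = []
    if n_inside > 0:
        if spec.planted_target is None or spec.planted_target not in collection.intervals:
            raise ValueError("fraction_inside > 0 requires a planted_target in the collection")
        target_ivs = collection.intervals[spec.planted_target]
        if not target_ivs:
            raise ValueError("planted target profile has no intervals")
        for _ in range(n_inside):
            base = target_ivs[int(rng.integers(0, len(target_ivs)))]
            # anchor the query inside the target interval where possible
            lo = base.start
            hi = max(lo, base.end - qlen)
            start = int(rng.integers(lo, hi + 1))
            out.append(GenomicInterval(base.chrom, start, start + qlen))
    qspec = FixtureSpec(
        genome_size=spec.genome_size,
        chromosomes=spec.chromosomes,
        interval_length=qlen,
        planted_target=None,
        seed=spec.seed,
    )
    out.extend(_random_intervals(qspec, rng, n_outside))
    return out
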