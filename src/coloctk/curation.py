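"""Profile collection curation: metadata manifest, tissue hierarchy,
replicate grouping, and outlier-profile removal.

Profiles are grouped by (source, assay type, tissue/cell type, biological
target); members of a group are replicates of one biological signal.  For
each group with at least three profiles a pairwise similarity matrix of
combo scores is built, profiles are clustered hierarchically (Euclidean
distance between matrix rows, average linkage), the tree is cut with the
inconsistency-coefficient criterion, and only the largest cluster is
retained — members outside it are treated as outliers and excluded from
colocalization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from . import stats
from .intervals import GenomicInterval, build_index, count_overlaps, parse_bed

__all__ = [
    "CATEGORIES",
    "Profile",
    "ProfileGroup",
    "TissueNode",
    "TissueHierarchy",
    "load_manifest",
    "group_profiles",
    "pairwise_similarity",
    "remove_outliers",
    "load_tissue_hierarchy",
]

#: The five profile categories.
CATEGORIES = frozenset(
    {
        "transcriptional_regulator",
        "histone_modification",
        "chromatin_accessibility",
        "transcriptional_event",
        "chromatin_segmentation",
    }
)

MANIFEST_COLUMNS = [
    "profile_id",
    "source",
    "assay_type",
    "category",
    "tissue",
    "sub_tissue",
    "cell_type",
    "target",
    "path",
]


@dataclass(frozen=True)
class Profile:
    """One epigenomic interval profile plus its curation metadata."""

    profile_id: str
    source: str
    assay_type: str
    category: str
    tissue: str
    target: str
    path: str
    sub_tissue: str | None = None
    cell_type: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {sorted(CATEGORIES)}"
            )

    @property
    def group_id(self) -> str:
        """Deterministic group key: source + assay type + tissue/cell type + target."""
        cell = self.cell_type if self.cell_type else self.tissue
        return "|".join(
            s.lower() for s in (self.source, self.assay_type, cell, self.target)
        )

    def load_intervals(self) -> list[GenomicInterval]:
        p = Path(self.path)
        if not p.exists():
            raise FileNotFoundError(f"profile {self.profile_id}: missing file {self.path}")
        try:
            intervals, _ = parse_bed(p)
        except ValueError:
            intervals = []  # empty profiles are legal
        return intervals


@dataclass
class ProfileGroup:
    """A set of replicate profiles sharing one group identifier."""

    group_id: str
    members: list[Profile]
    retained: list[Profile] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.retained:
            self.retained = list(self.members)

    @property
    def removed(self) -> list[Profile]:
        kept = {p.profile_id for p in self.retained}
        return [p for p in self.members if p.profile_id not in kept]


@dataclass(frozen=True)
class TissueNode:
    tissue_id: str
    parent: str | None = None
    children: tuple[str, ...] = ()


class TissueHierarchy:
    """Two-level tissue -> sub-tissue forest with selection expansion."""

    def __init__(self, nodes: Sequence[TissueNode]):
        self.nodes = {n.tissue_id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise ValueError("duplicate tissue identifiers in hierarchy")

    def __contains__(self, tissue_id: str) -> bool:
        return tissue_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def parent_of(self, tissue_id: str) -> str | None:
        return self.nodes[tissue_id].parent

    def expand(self, selection: Sequence[str]) -> frozenset[str]:
        """Expand a tissue selection to include all sub-tissues of selected tissues."""
        out: set[str] = set()
        for tid in selection:
            if tid not in self.nodes:
                raise KeyError(f"unknown tissue {tid!r}")
            out.add(tid)
            out.update(self.nodes[tid].children)
        return frozenset(out)

    @property
    def main_tissues(self) -> list[str]:
        return sorted(t for t, n in self.nodes.items() if n.parent is None)


def load_tissue_hierarchy(source) -> TissueHierarchy:
    """Load a tissue hierarchy from YAML mapping tissue -> list of sub-tissues.

    Rejects duplicate identifiers and nesting deeper than two levels
    (sub-tissues must be plain strings, not mappings).
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        data = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, dict):
        data = source
    else:
        data = yaml.safe_load(str(source))
    if not isinstance(data, dict):
        raise ValueError("tissue hierarchy must be a mapping tissue -> [sub-tissues]")
    nodes: list[TissueNode] = []
    seen: set[str] = set()
    for tissue, subs in data.items():
        subs = subs or []
        if not isinstance(subs, list) or any(not isinstance(s, str) for s in subs):
            raise ValueError(
                f"tissue {tissue!r}: sub-tissues must be a flat list of names "
                "(hierarchy depth is limited to two levels)"
            )
        for tid in [tissue, *subs]:
            if tid in seen:
                raise ValueError(f"duplicate tissue identifier {tid!r}")
            seen.add(tid)
        nodes.append(TissueNode(tissue, parent=None, children=tuple(subs)))
        nodes.extend(TissueNode(s, parent=tissue) for s in subs)
    return TissueHierarchy(nodes)


def load_manifest(
    path, hierarchy: TissueHierarchy | None = None, check_files: bool = True
) -> list[Profile]:
    """Load and validate a tab-separated profile manifest.

    Required columns: profile_id, source, assay_type, category, tissue,
    sub_tissue, cell_type, target, path (relative paths resolved against
    the manifest's directory).  Rows with unknown categories, tissues not
    in ``hierarchy``, or missing interval files are rejected with their
    line number in the error message.
    """
    path = Path(path)
    base = path.parent
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in MANIFEST_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"manifest missing required column(s): {', '.join(missing)}")
        profiles: list[Profile] = []
        errors: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            bed_path = base / row["path"] if not Path(row["path"]).is_absolute() else Path(row["path"])
            try:
                profile = Profile(
                    profile_id=row["profile_id"],
                    source=row["source"],
                    assay_type=row["assay_type"],
                    category=row["category"],
                    tissue=row["tissue"],
                    sub_tissue=row["sub_tissue"] or None,
                    cell_type=row["cell_type"] or None,
                    target=row["target"],
                    path=str(bed_path),
                )
            except ValueError as e:
                errors.append(f"line {lineno}: {e}")
                continue
            if hierarchy is not None:
                for tid in filter(None, (profile.tissue, profile.sub_tissue)):
                    if tid not in hierarchy:
                        errors.append(f"line {lineno}: tissue {tid!r} not in hierarchy")
                        profile = None
                        break
            if profile is None:
                continue
            if check_files and not bed_path.exists():
                errors.append(f"line {lineno}: missing interval file {bed_path}")
                continue
            profiles.append(profile)
    if errors:
        raise ValueError("manifest validation failed:\n" + "\n".join(errors))
    return profiles


def group_profiles(profiles: Sequence[Profile]) -> list[ProfileGroup]:
    """Partition profiles into replicate groups by their group key.

    The result is deterministic: groups sorted by group_id, members in
    input order.
    """
    by_key: dict[str, list[Profile]] = {}
    for p in profiles:
        by_key.setdefault(p.group_id, []).append(p)
    return [ProfileGroup(gid, members) for gid, members in sorted(by_key.items())]


def pairwise_similarity(
    profiles: Sequence[Profile],
    genome_size: int,
    intervals: Sequence[Sequence[GenomicInterval]] | None = None,
) -> np.ndarray:
    """Symmetric pairwise similarity matrix of capped combo scores.

    S[i, j] for i != j is the mean of the two directed combo scores
    (profile i as query against profile j, and vice versa); the diagonal
    is set to the score cap so self-similarity dominates every row.
    Pre-loaded ``intervals`` may be passed to avoid re-reading files.
    """
    n = len(profiles)
    if n < 2:
        raise ValueError("pairwise similarity needs at least two profiles")
    if intervals is None:
        intervals = [p.load_intervals() for p in profiles]
    indexes = [build_index(ivs) for ivs in intervals]
    S = np.full((n, n), stats.COMBO_CAP)
    for i in range(n):
        for j in range(i + 1, n):
            s_ij = _directed_combo(intervals[i], indexes[j], genome_size)
            s_ji = _directed_combo(intervals[j], indexes[i], genome_size)
            S[i, j] = S[j, i] = 0.5 * (s_ij + s_ji)
    return S


def _directed_combo(query, index, genome_size: int) -> float:
    if not query and index.count == 0:
        return 0.0
    obs = count_overlaps(query, index).pairs
    mean_size = stats.mean_interval_size(
        len(query), sum(iv.length for iv in query), index.count, index.total_length
    )
    table = stats.build_contingency(len(query), index.count, obs, genome_size, mean_size)
    p = stats.fisher_exact_two_tailed(table)
    return stats.combo_score(p, stats.odds_ratio(table))


def remove_outliers(
    group: ProfileGroup,
    genome_size: int,
    inconsistency_threshold: float = 1.5,
    depth: int = 4,
    linkage_method: str = "average",
    intervals: Sequence[Sequence[GenomicInterval]] | None = None,
) -> ProfileGroup:
    """Drop outlier members of a replicate group by cluster analysis.

    For groups of at least three members: build the pairwise combo-score
    similarity matrix, cluster its rows hierarchically (Euclidean distance,
    ``linkage_method`` linkage), cut the dendrogram where the inconsistency
    coefficient (computed over ``depth`` levels) exceeds the threshold, and
    retain the largest resulting cluster.  Equal-sized largest clusters are
    broken by keeping the one containing the member with highest mean
    similarity to all others.  Smaller groups are returned unchanged.
    """
    members = group.members
    if len(members) < stats.MIN_GROUP_SIZE:
        return ProfileGroup(group.group_id, list(members), list(members))

    S = pairwise_similarity(members, genome_size, intervals=intervals)
    dist = pdist(S, metric="euclidean")
    Z = linkage(dist, method=linkage_method)
    labels = fcluster(Z, t=inconsistency_threshold, criterion="inconsistent", depth=depth)

    mean_sim = (S.sum(axis=1) - np.diag(S)) / (len(members) - 1)
    sizes: dict[int, int] = {}
    for lab in labels:
        sizes[lab] = sizes.get(lab, 0) + 1
    best_size = max(sizes.values())
    candidates = [lab for lab, sz in sizes.items() if sz == best_size]
    if len(candidates) > 1:
        # tie: keep the cluster holding the member most similar to everyone
        best_lab = max(
            candidates,
            key=lambda lab: max(mean_sim[i] for i in range(len(members)) if labels[i] == lab),
        )
    else:
        best_lab = candidates[0]

    retained = [p for p, lab in zip(members, labels) if lab == best_lab]
    return ProfileGroup(group.group_id, list(members), retained)
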