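"""Cross-grade malignancy signature by thresholded DE-list intersection.

Aggressive meningioma subgroups (recurrent / malignantly progressing WHO I
and II tumors, and WHO III tumors) are each contrasted against benign
non-recurrent WHO I tumors; genes passing every contrast's (p, fold-change)
cutoff in a consistent direction form the directional signature. Venn-region
bookkeeping is kept per direction so the per-comparison list sizes remain
auditable partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io import ValidationError
from .differential import passes_thresholds

UP = "up"
DOWN = "down"


def de_gene_list(
    results: pd.DataFrame, p_threshold: float, fc_threshold: float
) -> tuple[set[str], set[str]]:
    """Split a DE result frame into (up, down) gene sets at strict cutoffs.

    up: p < p_threshold and FC > fc_threshold; down: p < p_threshold and
    FC < 1/fc_threshold. The inequalities are strict, so boundary genes
    (p exactly at the cutoff) are excluded.
    """
    if results.empty:
        return set(), set()
    sig = results["p_value"] < p_threshold
    up = set(results.index[sig & (results["fold_change_linear"] > fc_threshold)])
    down = set(results.index[sig & (results["fold_change_linear"] < 1.0 / fc_threshold)])
    return up, down


@dataclass
class Signature:
    """Directional gene set with per-gene Venn provenance.

    ``entries`` maps gene -> (direction, frozenset of comparison names the
    gene was significant in). Signature membership requires presence in all
    comparisons with one direction; ``venn_counts`` records every region of
    the per-direction Venn diagrams (keys: (direction, frozenset of names)).
    """

    entries: dict[str, tuple[str, frozenset[str]]]
    comparisons: tuple[str, ...]
    venn_counts: dict[tuple[str, frozenset[str]], int]
    conflicting: set[str] = field(default_factory=set)

    @property
    def genes(self) -> set[str]:
        return set(self.entries)

    def genes_by_direction(self, direction: str) -> set[str]:
        return {g for g, (d, _) in self.entries.items() if d == direction}

    @property
    def n_up(self) -> int:
        return len(self.genes_by_direction(UP))

    @property
    def n_down(self) -> int:
        return len(self.genes_by_direction(DOWN))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "direction": d, "member_of": "|".join(sorted(m))}
            for g, (d, m) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "direction", "member_of"])

    def venn_table(self) -> pd.DataFrame:
        rows = [
            {"direction": d, "region": "|".join(sorted(names)), "count": c}
            for (d, names), c in sorted(
                self.venn_counts.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]))
            )
        ]
        return pd.DataFrame(rows, columns=["direction", "region", "count"])


def _venn_regions(
    lists: dict[str, set[str]]
) -> dict[frozenset[str], set[str]]:
    """Partition the union of the sets into exclusive Venn regions."""
    names = list(lists)
    regions: dict[frozenset[str], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(lists[n] for n in combo))
            outside = set.union(set(), *(lists[n] for n in names if n not in combo))
            regions[frozenset(combo)] = inside - outside
    return regions


def intersect_signature(lists: dict[str, tuple[set[str], set[str]]]) -> Signature:
    """Intersect per-comparison (up, down) lists into the shared signature.

    A gene enters the signature when it appears in every comparison's up
    list (direction 'up') or every down list ('down'). Genes that are up in
    one comparison and down in another are excluded and reported in
    ``conflicting``.
    """
    if len(lists) < 2:
        raise ValidationError("need at least two comparisons to intersect")
    names = tuple(lists)
    ups = {n: set(lists[n][0]) for n in names}
    downs = {n: set(lists[n][1]) for n in names}

    up_core = set.intersection(*ups.values())
    down_core = set.intersection(*downs.values())
    # any gene called up in one comparison and down in another is unusable
    conflicting = set.union(*ups.values()) & set.union(*downs.values())
    up_core -= conflicting
    down_core -= conflicting

    entries: dict[str, tuple[str, frozenset[str]]] = {}
    for g in up_core:
        entries[g] = (UP, frozenset(names))
    for g in down_core:
        entries[g] = (DOWN, frozenset(names))

    venn: dict[tuple[str, frozenset[str]], int] = {}
    for direction, sets in ((UP, ups), (DOWN, downs)):
        for region, members in _venn_regions(sets).items():
            venn[(direction, region)] = len(members)
    return Signature(entries, names, venn, conflicting)


def build_signature(
    results: dict[str, pd.DataFrame],
    thresholds: dict[str, tuple[float, float]],
) -> Signature:
    """Convenience wrapper: threshold each result frame, then intersect."""
    lists = {
        name: de_gene_list(results[name], *thresholds[name]) for name in results
    }
    return intersect_signature(lists)


def select_candidates(
    whoIII_vs_I: pd.DataFrame,
    subgroup_results: dict[str, pd.DataFrame],
    p1: float = 0.01,
    p2: float = 0.01,
    fc2: float = 1.25,
    min_subgroup_hits: int = 2,
    manual_additions: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Select top validation candidates from the grade III vs I contrast.

    A gene qualifies when (a) p < ``p1`` in WHO III vs I and its fold change
    lies above the 90th or below the 10th percentile of the whole FC
    distribution of that contrast, and (b) it passes p < ``p2`` with |FC|
    beyond ``fc2`` (two-sided) in at least ``min_subgroup_hits`` of the
    subgroup comparisons. Percentiles use linear interpolation. Genes on the
    ``manual_additions`` allow-list (e.g. a literature-driven kinase) are
    appended and flagged; they bypass the automatic filter.
    """
    if len(whoIII_vs_I) < 10:
        raise ValidationError("need >= 10 genes to define FC percentiles")
    fc = whoIII_vs_I["fold_change_linear"].to_numpy(float)
    q10, q90 = np.quantile(fc, [0.10, 0.90])  # linear interpolation
    extreme = (fc > q90) | (fc < q10)
    primary = (whoIII_vs_I["p_value"].to_numpy() < p1) & extreme

    hits = pd.Series(0, index=whoIII_vs_I.index)
    for res in subgroup_results.values():
        mask = passes_thresholds(res, p2, fc2)
        hits = hits.add(mask.reindex(hits.index, fill_value=False).astype(int),
                        fill_value=0)
    selected = whoIII_vs_I.index[primary & (hits >= min_subgroup_hits).to_numpy()]

    rows = [{"gene": g, "manual": False} for g in selected]
    for g in sorted(set(manual_additions) - set(selected)):
        rows.append({"gene": g, "manual": True})
    out = pd.DataFrame(rows, columns=["gene", "manual"])
    return out.sort_values(["manual", "gene"]).reset_index(drop=True)
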