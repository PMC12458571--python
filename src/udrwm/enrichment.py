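"""Regional enrichment of t-maps: running K-S statistic and ROI permutation test.

Two complementary questions about a voxel-wise |t| map:

*Which regions does the map concentrate in?*  Voxels of the labeled atlas
are ranked by t descending; for each region the running curve
``k(n)/V_r - n/N`` (region hits among the top n, GSEA-style) is traced and
its maximum is the region's K-S enrichment value.

*Is the concentration significant?*  The observed region statistic is the
median |t| inside the region; a null is built by permuting t-values across
all labeled voxels (breaking spatial association while keeping the value
distribution), with add-one-smoothed p-values
``(1 + #{S_perm >= S_obs}) / (n_perm + 1)`` and Bonferroni correction over
the regions actually tested.

Ties in the ranking are broken by the fixed array scan order (documented in
:mod:`udrwm.volumes`) unless a tie-break seed is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import LabelAtlas

__all__ = [
    "KSResult",
    "PermutationResult",
    "rank_voxels",
    "ks_statistic",
    "ks_enrichment",
    "roi_permutation_test",
    "tissue_enrichment",
]


def _tmap_array(tmap) -> np.ndarray:
    if hasattr(tmap, "data"):
        arr = tmap.data
        arr = arr.data if hasattr(arr, "data") and not isinstance(arr, np.ndarray) else arr
        return np.asarray(arr, dtype=np.float64)
    return np.asarray(tmap, dtype=np.float64)


@dataclass
class KSResult:
    table: pd.DataFrame  # region_id, region_name, n_voxels, ks
    n_total: int

    def top_region(self) -> int:
        return int(self.table.sort_values("ks", ascending=False).iloc[0]["region_id"])


@dataclass
class PermutationResult:
    table: pd.DataFrame  # region_id, region_name, n_voxels, s_obs, p_raw, p_bonf
    n_perm: int
    seed: int
    bonferroni_factor: int


def rank_voxels(tmap, atlas: LabelAtlas, tie_break_seed: int | None = None):
    """Rank all atlas-labeled voxels by t descending.

    Returns ``(order, t_flat, labels_flat)`` where ``order`` indexes the
    labeled voxels (in scan order) from highest to lowest t.  Ties keep
    scan order (stable sort); a ``tie_break_seed`` shuffles tied voxels
    randomly instead, for tie-bias checks.
    """
    t = _tmap_array(tmap)
    if t.shape != atlas.shape:
        raise ValueError(f"t-map shape {t.shape} != atlas shape {atlas.shape}")
    labeled = atlas.data.ravel() > 0
    if not labeled.any():
        raise ValueError("atlas has no labeled voxels")
    t_flat = t.ravel()[labeled]
    labels_flat = atlas.data.ravel()[labeled]
    if tie_break_seed is None:
        order = np.argsort(-t_flat, kind="stable")
    else:
        rng = np.random.default_rng(tie_break_seed)
        jitter = rng.permutation(t_flat.size)
        order = np.lexsort((jitter, -t_flat))
    return order, t_flat, labels_flat


def ks_statistic(ranked_membership: np.ndarray) -> float:
    """K-S enrichment value from a boolean membership vector in rank order.

    ``ranked_membership[i]`` says whether the i-th ranked voxel belongs to
    the region.  The value is ``max_n (k(n)/V_r - n/N)``.
    """
    member = np.asarray(ranked_membership, dtype=bool)
    N = member.size
    V = int(member.sum())
    if V == 0:
        raise ValueError("region has no voxels in the ranking")
    k = np.cumsum(member)
    n = np.arange(1, N + 1)
    return float(np.max(k / V - n / N))


def ks_enrichment(tmap, atlas: LabelAtlas, tie_break_seed: int | None = None) -> KSResult:
    """K-S enrichment value for every atlas region."""
    order, _, labels_flat = rank_voxels(tmap, atlas, tie_break_seed)
    ranked_labels = labels_flat[order]
    rows = []
    for r in atlas.region_ids:
        member = ranked_labels == r
        rows.append(
            {
                "region_id": r,
                "region_name": atlas.labels.get(r, f"region_{r}"),
                "n_voxels": int(member.sum()),
                "ks": ks_statistic(member),
            }
        )
    return KSResult(table=pd.DataFrame(rows), n_total=int(labels_flat.size))


def roi_permutation_test(
    tmap,
    atlas: LabelAtlas,
    n_perm: int = 5000,
    seed: int = 0,
    statistic: str = "median",
) -> PermutationResult:
    """Permutation test of per-region median |t| against a spatial null.

    t-values are shuffled within the combined labeled mask; each of the
    ``n_perm`` shuffles yields one null statistic per region.  The
    attainable p floor is ``1/(n_perm+1)``; Bonferroni uses the number of
    regions tested in this call.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t = np.abs(_tmap_array(tmap))
    if t.shape != atlas.shape:
        raise ValueError(f"t-map shape {t.shape} != atlas shape {atlas.shape}")
    labeled = atlas.data.ravel() > 0
    t_flat = t.ravel()[labeled]
    labels_flat = atlas.data.ravel()[labeled]

    regions = [r for r in atlas.region_ids if (labels_flat == r).any()]
    stat = np.median if statistic == "median" else np.mean
    masks = {r: labels_flat == r for r in regions}
    s_obs = {r: float(stat(t_flat[masks[r]])) for r in regions}

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF3]))
    exceed = {r: 0 for r in regions}
    for _ in range(n_perm):
        perm = rng.permutation(t_flat)
        for r in regions:
            if stat(perm[masks[r]]) >= s_obs[r]:
                exceed[r] += 1

    R = len(regions)
    rows = []
    for r in regions:
        p_raw = (1 + exceed[r]) / (n_perm + 1)
        rows.append(
            {
                "region_id": r,
                "region_name": atlas.labels.get(r, f"region_{r}"),
                "n_voxels": int(masks[r].sum()),
                "s_obs": s_obs[r],
                "p_raw": p_raw,
                "p_bonf": min(1.0, R * p_raw),
            }
        )
    return PermutationResult(table=pd.DataFrame(rows), n_perm=n_perm, seed=seed, bonferroni_factor=R)


def tissue_enrichment(tmap, tissue_atlas: LabelAtlas, tie_break_seed: int | None = None) -> KSResult:
    """K-S enrichment across coarse tissue classes (same machinery as regions)."""
    if tissue_atlas.n_regions < 2:
        raise ValueError("tissue atlas needs at least 2 classes")
    return ks_enrichment(tmap, tissue_atlas, tie_break_seed)
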