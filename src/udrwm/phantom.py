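"""Synthetic FA-like phantom cohorts with known latent structure.

The phantom emulates the statistical skeleton of a registered FA cohort:
an ellipsoidal "brain" mask, a handful of disjoint ellipsoidal regions
standing in for white-matter tracts, and per-subject volumes generated by a
linear latent-factor model

    x_i(v) = clip( mu + sum_k z_ik * w_k * B_k(v) + eps_iv , 0, 1 )

with z_ik ~ N(0,1) subject scores, B_k the indicator of factor k's
region(s), w_k the loading weight, and i.i.d. Gaussian voxel noise.
Region-indicator loadings keep the ground truth for perturbation maps and
regional enrichment analytically known: factor k "lives" in exactly its
assigned region(s).

Also provides synthetic gene networks with planted overlapping node sets
and synthetic gene-property tables, so the network and gene-level
statistics are testable without external resources.

Determinism: every generator takes a seed; per-subject draws use spawned
child streams so subject i's volume does not depend on the cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .volumes import BrainMask, LabelAtlas, Volume3D, write_volume

__all__ = [
    "PhantomSpec",
    "PhantomCohort",
    "make_atlas",
    "simulate_cohort",
    "simulate_paired_modalities",
    "simulate_network",
    "simulate_geneprop",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom generator.

    baseline/noise_sd/loading are on the FA scale (unitless, [0,1]):
    baseline 0.45 is a typical white-matter FA value, loading 0.15 gives a
    per-voxel factor effect an order of magnitude above the 0.02 voxel
    noise, so planted factors dominate regional variance as tract-level
    anatomy does in real cohorts.
    """

    grid: tuple[int, int, int] = (32, 40, 32)
    n_regions: int = 6
    n_latents: int = 4
    loading: float = 0.15
    baseline: float = 0.45
    noise_sd: float = 0.02
    seed: int = 0
    # factor k -> tuple of region ids (1-based); default assigns factor k
    # to region k+1, leaving any extra regions unloaded.
    loading_map: dict[int, tuple[int, ...]] | None = None

    def factor_regions(self, k: int) -> tuple[int, ...]:
        if self.loading_map is not None:
            return self.loading_map[k]
        return (k + 1,)


@dataclass
class PhantomCohort:
    volumes: list[Volume3D]
    mask: BrainMask
    atlas: LabelAtlas
    true_latents: pd.DataFrame  # n x K, index = subject ids
    spec: PhantomSpec

    @property
    def n(self) -> int:
        return len(self.volumes)

    def data_array(self) -> np.ndarray:
        """Stack as (n, nx, ny, nz) float64."""
        return np.stack([v.data for v in self.volumes])

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_volume(Volume3D(self.mask.data.astype(float), self.mask.affine), outdir / "mask.nii.gz")
        write_volume(Volume3D(self.atlas.data.astype(float), self.atlas.affine), outdir / "atlas.nii.gz", dtype=np.int16)
        for i, vol in enumerate(self.volumes):
            write_volume(vol, outdir / f"subj{i:04d}.nii.gz")
        self.true_latents.to_csv(outdir / "true_latents.tsv", sep="\t")
        return outdir


def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return d <= 1.0


def make_atlas(spec: PhantomSpec) -> tuple[BrainMask, LabelAtlas]:
    """Ellipsoidal brain mask with ``n_regions`` disjoint ellipsoidal ROIs.

    Region centers are drawn inside the mask with rejection sampling;
    deterministic given ``spec.seed``.
    """
    shape = tuple(spec.grid)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA71A5]))
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.45
    mask_arr = _ellipsoid(shape, center, semi)
    if not mask_arr.any():
        raise ValueError("grid too small for a brain mask")

    labels = np.zeros(shape, dtype=np.int32)
    # region semi-axes shrink gently with region count so 6 regions fit a 32-grid
    reg_semi = np.maximum(np.asarray(shape) * (0.16 - 0.004 * spec.n_regions), 1.6)
    placed = 0
    attempts = 0
    max_attempts = 400 * max(spec.n_regions, 1)
    while placed < spec.n_regions:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_regions} disjoint regions after {max_attempts} "
                "attempts; use a larger grid or fewer regions"
            )
        c = center + (rng.uniform(-0.62, 0.62, size=3)) * semi
        blob = _ellipsoid(shape, c, reg_semi)
        if not blob.any():
            continue
        if (blob & ~mask_arr).any():  # must sit fully inside the brain
            continue
        if (blob & (labels > 0)).any():  # disjoint from earlier regions
            continue
        placed += 1
        labels[blob] = placed

    affine = np.eye(4)
    mask = BrainMask(data=mask_arr.astype(np.uint8), affine=affine)
    atlas = LabelAtlas(
        data=labels,
        affine=affine,
        labels={r: f"roi_{r:02d}" for r in range(1, spec.n_regions + 1)} if spec.n_regions else {},
    )
    return mask, atlas


def _factor_fields(spec: PhantomSpec, atlas: LabelAtlas) -> np.ndarray:
    """(K, nx, ny, nz) indicator loading fields B_k."""
    fields = np.zeros((spec.n_latents, *spec.grid))
    for k in range(spec.n_latents):
        for r in spec.factor_regions(k):
            fields[k][atlas.data == r] = 1.0
    return fields


def _subject_volume(
    mu: float,
    z_row: np.ndarray,
    w: float,
    fields: np.ndarray,
    noise_sd: float,
    mask_arr: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    x = np.full(fields.shape[1:], mu)
    x += np.tensordot(z_row * w, fields, axes=(0, 0))
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=x.shape)
    x = np.clip(x, 0.0, 1.0)
    x[~mask_arr] = 0.0
    return x


def simulate_cohort(spec: PhantomSpec, n: int) -> PhantomCohort:
    """Generate ``n`` subject volumes plus the true n x K latent table."""
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mask, atlas = make_atlas(spec)
    fields = _factor_fields(spec, atlas)
    mask_arr = mask.data.astype(bool)

    root = np.random.SeedSequence([spec.seed, 0xC0307])
    children = root.spawn(n)
    z = np.empty((n, spec.n_latents))
    vols: list[Volume3D] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        z[i] = rng.standard_normal(spec.n_latents)
        x = _subject_volume(spec.baseline, z[i], spec.loading, fields, spec.noise_sd, mask_arr, rng)
        vols.append(Volume3D(data=x, affine=np.eye(4), name=f"subj{i:04d}"))

    latents = pd.DataFrame(
        z,
        index=pd.Index([f"subj{i:04d}" for i in range(n)], name="subject"),
        columns=[f"factor_{k}" for k in range(spec.n_latents)],
    )
    return PhantomCohort(volumes=vols, mask=mask, atlas=atlas, true_latents=latents, spec=spec)


def simulate_paired_modalities(
    spec: PhantomSpec, n: int, shared_frac: float
) -> tuple[PhantomCohort, PhantomCohort]:
    """Two cohorts on the same grid whose latent factors overlap partially.

    Exactly ``round(shared_frac * K)`` factor columns are identical between
    the modalities; the remaining columns are drawn independently.  The
    second modality uses its own noise stream.
    """
    if not 0.0 <= shared_frac <= 1.0:
        raise ValueError("shared_frac must be in [0, 1]")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    K = spec.n_latents
    n_shared = int(round(shared_frac * K))

    cohort_x = simulate_cohort(spec, n)
    mask, atlas = cohort_x.mask, cohort_x.atlas
    fields = _factor_fields(spec, atlas)
    mask_arr = mask.data.astype(bool)

    root = np.random.SeedSequence([spec.seed, 0x9A17ED])
    children = root.spawn(n)
    zx = cohort_x.true_latents.to_numpy()
    zy = np.empty_like(zx)
    vols: list[Volume3D] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        fresh = rng.standard_normal(K)
        zy[i] = np.where(np.arange(K) < n_shared, zx[i], fresh)
        x = _subject_volume(spec.baseline, zy[i], spec.loading, fields, spec.noise_sd, mask_arr, rng)
        vols.append(Volume3D(data=x, affine=np.eye(4), name=f"subj{i:04d}"))

    latents_y = pd.DataFrame(zy, index=cohort_x.true_latents.index.copy(), columns=cohort_x.true_latents.columns.copy())
    cohort_y = PhantomCohort(volumes=vols, mask=mask, atlas=atlas, true_latents=latents_y, spec=spec)
    return cohort_x, cohort_y


def simulate_network(
    n_genes: int,
    edge_prob: float,
    planted_sets: list[tuple[str, int, int]] | None = None,
    seed: int = 0,
) -> tuple[nx.Graph, dict[str, set[str]]]:
    """Erdos-Renyi gene graph plus node sets with exact pairwise overlaps.

    ``planted_sets`` is a list of ``(name, size, overlap)`` triples; the
    first set is the anchor, and each later set shares exactly ``overlap``
    members with the anchor set (overlapping member blocks are disjoint
    between later sets, so anchor/other overlaps are exact by
    construction).
    """
    genes = [f"g{i:05d}" for i in range(n_genes)]
    g = nx.gnp_random_graph(n_genes, edge_prob, seed=int(seed))
    g = nx.relabel_nodes(g, dict(enumerate(genes)))
    g.add_nodes_from(genes)

    sets: dict[str, set[str]] = {}
    if planted_sets:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E75]))
        order = list(rng.permutation(n_genes))
        name0, size0, _ = planted_sets[0]
        if size0 > n_genes:
            raise ValueError("planted set larger than gene universe")
        anchor_idx = order[:size0]
        sets[name0] = {genes[i] for i in anchor_idx}
        pool = order[size0:]  # indices not in the anchor
        anchor_pos = 0
        for name, size, overlap in planted_sets[1:]:
            if overlap > min(size, size0):
                raise ValueError(f"set {name}: overlap {overlap} exceeds min set size")
            if anchor_pos + overlap > size0 or size - overlap > len(pool):
                raise ValueError(f"set {name}: infeasible size/overlap for universe {n_genes}")
            members = [genes[i] for i in anchor_idx[anchor_pos : anchor_pos + overlap]]
            anchor_pos += overlap
            members += [genes[i] for i in pool[: size - overlap]]
            pool = pool[size - overlap :]
            sets[name] = set(members)
    return g, sets


def simulate_geneprop(
    n_genes: int, beta1: float, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene p-value table plus expression table under the gene-property model.

    Z_g = beta1 * E_g + N(0,1), p_g = 1 - Phi(Z_g); E is the focal-tissue
    expression (standardized), with an average-expression column and a
    gene-size covariate that are independent of Z under the null.
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6E9E]))
    genes = [f"g{i:05d}" for i in range(n_genes)]
    expr = rng.standard_normal(n_genes)
    avg_expr = rng.standard_normal(n_genes)
    gene_size = rng.lognormal(mean=3.0, sigma=0.5, size=n_genes)
    z = beta1 * expr + rng.standard_normal(n_genes)
    p = 1.0 - norm.cdf(z)

    pvals = pd.DataFrame({"gene": genes, "p": p}).set_index("gene")
    expr_tab = pd.DataFrame(
        {"gene": genes, "expr": expr, "avg_expr": avg_expr, "gene_size": gene_size}
    ).set_index("gene")
    return pvals, expr_tab


def write_network(g: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")
    return path


def read_network(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 2:
                g.add_edge(parts[0], parts[1])
    return g


def write_gene_sets(sets: dict[str, set[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write(name + "\t" + "\t".join(sorted(members)) + "\n")
    return path


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts and parts[0]:
                sets[parts[0]] = set(p for p in parts[1:] if p)
    return sets
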