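"""Spatial colocalization: region masks, nearest-neighbor distances,
permutation nulls, and the genome-wide consistent-proximity screen.

A *section* is an :class:`anndata.AnnData` of spots x genes with 2-D
coordinates in ``obsm["spatial"]`` (x, y in section units) and a section
identifier in ``uns["section_id"]``.  Expression values may be raw counts
or already-normalized values; every statistic here is rank- or
threshold-based, so only the ordering of values within a gene matters.

The proximity statistic for a test gene against an anchor gene is the mean
Euclidean distance from each of the test gene's high-expression spots to
the nearest anchor high-expression spot (high = top 25% of spots by that
gene's expression).  Its null distribution is obtained by shuffling the
test gene's expression values across spots — the value multiset, and hence
the high-region size, is preserved — while the anchor region stays fixed.
Empirical p-values use the (1 + #{null <= observed}) / (1 + B) convention
and are therefore never zero.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from scipy.spatial import cKDTree

from .errors import ConfigurationError, InputError
from .stratify import bh_adjust

logger = logging.getLogger(__name__)

SECTION_ID_KEY = "section_id"
SPATIAL_KEY = "spatial"

#: skip reasons attached to ProximityResult
SKIP_UNINFORMATIVE = "uninformative-distribution"
SKIP_TOO_FEW_SPOTS = "too-few-spots"
SKIP_ANCHOR_INVALID = "anchor-mask-invalid"

_EXHAUSTIVE_MAX_SPOTS = 8  # n! permutations enumerated up to this size

#: permutations whose per-spot distances feed the secondary Mann-Whitney
#: comparison; the empirical p always uses every permutation.  Capping the
#: pooled control sample keeps the rank test O(B_mwu * mask) while leaving
#: its null representative of the shuffled-expression distribution.
MWU_POOL_PERMUTATIONS = 50


@dataclass(frozen=True)
class RegionMask:
    """Top-fraction high-expression region for one gene in one section."""

    gene: str
    section_id: str
    members: np.ndarray            # positional spot indices, sorted
    threshold: float
    skipped: bool = False
    skip_reason: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ProximityResult:
    """Permutation-null proximity outcome for one gene in one section."""

    gene: str
    section_id: str
    d_obs: float = math.nan
    null_d: np.ndarray = field(default_factory=lambda: np.array([]))
    empirical_p: float = math.nan
    mwu_p: float = math.nan
    q: float = math.nan
    skipped: bool = False
    skip_reason: str | None = None


@dataclass
class ScreenResult:
    """Genome-wide consistent-proximity screen across sections."""

    per_gene: dict[str, list[ProximityResult]]
    consistent: list[str]          # genes with q <= alpha in every section
    ranking: pd.DataFrame          # consistent genes ranked by mean d_obs


def section_id(section: AnnData) -> str:
    return str(section.uns.get(SECTION_ID_KEY, "section"))


def _coords(section: AnnData) -> np.ndarray:
    if SPATIAL_KEY not in section.obsm:
        raise InputError("section is missing obsm['spatial'] coordinates")
    xy = np.asarray(section.obsm[SPATIAL_KEY], dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] != section.n_obs:
        raise InputError("coordinates must be one (x, y) pair per spot")
    return xy


def _gene_values(section: AnnData, gene: str) -> np.ndarray:
    if gene not in section.var_names:
        raise InputError(
            f"gene {gene!r} not present in section {section_id(section)!r}"
        )
    col = section[:, gene].X
    if sp.issparse(col):
        col = col.toarray()
    return np.asarray(col, dtype=float).ravel()


def high_region_mask(
    section: AnnData, gene: str, top_fraction: float = 0.25
) -> RegionMask:
    """Spots in the top ``top_fraction`` of a gene's expression.

    The threshold is the (1 - top_fraction) linear-interpolation quantile
    over all spots; members are spots at or above it.  If the threshold
    equals the gene's minimum the mask would cover every spot, which says
    nothing about localization: the gene is marked skipped with reason
    ``uninformative-distribution``.
    """
    if not 0 < top_fraction < 1:
        raise ConfigurationError(f"top_fraction must be in (0,1): {top_fraction}")
    sid = section_id(section)
    if section.n_obs < 4:
        return RegionMask(
            gene, sid, np.array([], dtype=int), math.nan,
            skipped=True, skip_reason=SKIP_TOO_FEW_SPOTS,
        )
    v = _gene_values(section, gene)
    thr = float(np.quantile(v, 1.0 - top_fraction))
    if thr <= v.min():
        return RegionMask(
            gene, sid, np.array([], dtype=int), thr,
            skipped=True, skip_reason=SKIP_UNINFORMATIVE,
        )
    members = np.flatnonzero(v >= thr)
    return RegionMask(gene, sid, members, thr)


def nn_distance(
    mask_a: RegionMask, mask_b: RegionMask, coords: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-spot nearest-neighbor distances from mask A into mask B.

    Returns the vector of Euclidean distances from each member of
    ``mask_a`` to its nearest member of ``mask_b`` and their arithmetic
    mean.  A spot belonging to both masks contributes zero.
    """
    if mask_a.section_id != mask_b.section_id:
        raise InputError(
            f"masks come from different sections: {mask_a.section_id!r} "
            f"vs {mask_b.section_id!r}"
        )
    if mask_a.skipped or mask_b.skipped or not mask_a.size or not mask_b.size:
        raise InputError("nn_distance requires two nonempty, unskipped masks")
    tree = cKDTree(coords[mask_b.members])
    d, _ = tree.query(coords[mask_a.members])
    d = np.asarray(d, dtype=float)
    return d, float(d.mean())


def empirical_pvalue(d_obs: float, null_d: np.ndarray) -> float:
    """(1 + #{null <= observed}) / (1 + B); lies in [1/(B+1), 1]."""
    null_d = np.asarray(null_d, dtype=float)
    b = len(null_d)
    if b < 1:
        raise ConfigurationError("empirical p-value needs at least 1 permutation")
    return (1.0 + float((null_d <= d_obs).sum())) / (1.0 + b)


def mwu_test(sample_a, sample_b) -> float:
    """One-sided Mann-Whitney p for "A stochastically smaller than B".

    Exact permutation enumeration when both samples have at most eight
    observations (ties handled through average ranks); tie-corrected
    normal approximation with continuity correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InputError("mwu_test requires two nonempty samples")
    if len(a) <= 8 and len(b) <= 8:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        w_obs = ranks[: len(a)].sum()
        eps = 1e-9
        count = total = 0
        for comb in itertools.combinations(range(len(pooled)), len(a)):
            total += 1
            if ranks[list(comb)].sum() <= w_obs + eps:
                count += 1
        return count / total
    res = stats.mannwhitneyu(a, b, alternative="less", method="asymptotic")
    return float(res.pvalue)


def _substream(seed: int, sid: str, gene: str) -> np.random.Generator:
    """Seeded RNG stable in (section, gene), independent of iteration order."""
    digest = hashlib.blake2b(f"{sid}|{gene}".encode(), digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest, "little")])
    )


def _null_statistics_values(
    values: np.ndarray,
    threshold: float,
    d_field: np.ndarray,
    B: int,
    rng: np.random.Generator,
    chunk: int = 512,
    mwu_pool: int = MWU_POOL_PERMUTATIONS,
) -> tuple[np.ndarray, np.ndarray]:
    """Null D statistics by shuffling a gene's values across spots.

    For each permutation, the shuffled values are re-thresholded at the
    (permutation-invariant) cutoff and the mean of the precomputed
    distance-to-anchor field over the resulting mask is recorded.  Per-spot
    distances from the first ``mwu_pool`` permutations are pooled for the
    secondary rank test.
    """
    null_d = np.empty(B)
    spot_dists: list[np.ndarray] = []
    done = 0
    while done < B:
        nb = min(chunk, B - done)
        perm = rng.permuted(np.tile(values, (nb, 1)), axis=1)
        masks = perm >= threshold
        sizes = masks.sum(axis=1)
        null_d[done : done + nb] = (d_field * masks).sum(axis=1) / sizes
        if done < mwu_pool:
            take = masks[: min(nb, mwu_pool - done)]
            spot_dists.append(np.broadcast_to(d_field, take.shape)[take])
        done += nb
    pooled = np.concatenate(spot_dists) if spot_dists else np.array([])
    return null_d, pooled


def _null_statistics_coordinates(
    test_members: np.ndarray,
    anchor_members: np.ndarray,
    coords: np.ndarray,
    B: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternative null: shuffle the coordinate assignment of all spots.

    Both masks keep their spot memberships while the coordinates are
    permuted jointly, so the geometry (not the expression coupling) is
    randomized.
    """
    n = coords.shape[0]
    null_d = np.empty(B)
    pooled = []
    for b in range(B):
        perm = rng.permutation(n)
        pc = coords[perm]
        tree = cKDTree(pc[anchor_members])
        d, _ = tree.query(pc[test_members])
        null_d[b] = d.mean()
        pooled.append(d)
    return null_d, np.concatenate(pooled)


def anchor_distance_field(section: AnnData, anchor_mask: RegionMask) -> np.ndarray:
    """Distance from every spot to its nearest anchor-high spot."""
    coords = _coords(section)
    tree = cKDTree(coords[anchor_mask.members])
    d, _ = tree.query(coords)
    return np.asarray(d, dtype=float)


def permutation_null(
    section: AnnData,
    anchor_gene: str,
    test_gene: str,
    B: int = 1000,
    seed: int = 0,
    top_fraction: float = 0.25,
    null_mode: str = "values",
    exhaustive: bool = False,
    rng: np.random.Generator | None = None,
    _anchor_mask: RegionMask | None = None,
    _d_field: np.ndarray | None = None,
) -> ProximityResult:
    """Proximity statistic with a shuffled-expression null for one gene.

    The anchor's high region is held fixed.  ``null_mode="values"``
    (default) shuffles the test gene's values across spots B times,
    preserving the value multiset; ``null_mode="coordinates"`` shuffles
    the coordinate assignment jointly instead.  ``exhaustive=True``
    enumerates every permutation of the value vector (sections of at most
    eight spots), replacing B.  Deterministic given the seed.
    """
    if B < 1:
        raise ConfigurationError(f"B must be >= 1, got {B}")
    if null_mode not in ("values", "coordinates"):
        raise ConfigurationError(f"unknown null_mode {null_mode!r}")
    sid = section_id(section)
    coords = _coords(section)

    anchor_mask = _anchor_mask or high_region_mask(section, anchor_gene, top_fraction)
    if anchor_mask.skipped:
        return ProximityResult(
            test_gene, sid, skipped=True, skip_reason=SKIP_ANCHOR_INVALID
        )
    test_mask = high_region_mask(section, test_gene, top_fraction)
    if test_mask.skipped:
        return ProximityResult(
            test_gene, sid, skipped=True, skip_reason=test_mask.skip_reason
        )

    d_field = (
        _d_field
        if _d_field is not None
        else anchor_distance_field(section, anchor_mask)
    )
    obs_dists = d_field[test_mask.members]
    d_obs = float(obs_dists.mean())

    values = _gene_values(section, test_gene)
    if exhaustive:
        if section.n_obs > _EXHAUSTIVE_MAX_SPOTS:
            raise ConfigurationError(
                f"exhaustive enumeration limited to {_EXHAUSTIVE_MAX_SPOTS} spots"
            )
        null_d = []
        pooled = []
        for perm in itertools.permutations(range(section.n_obs)):
            mask = values[list(perm)] >= test_mask.threshold
            dd = d_field[mask]
            null_d.append(dd.mean())
            pooled.append(dd)
        null_d = np.asarray(null_d)
        pooled = np.concatenate(pooled)
    else:
        if rng is None:
            rng = _substream(seed, sid, test_gene)
        if null_mode == "values":
            null_d, pooled = _null_statistics_values(
                values, test_mask.threshold, d_field, B, rng
            )
        else:
            null_d, pooled = _null_statistics_coordinates(
                test_mask.members, anchor_mask.members, coords, B, rng
            )

    return ProximityResult(
        gene=test_gene,
        section_id=sid,
        d_obs=d_obs,
        null_d=null_d,
        empirical_p=empirical_pvalue(d_obs, null_d),
        mwu_p=mwu_test(obs_dists, pooled),
    )


def spearman_coloc(section: AnnData, gene_a: str, gene_b: str) -> float:
    """Spearman rank correlation of two genes across spots.

    Average ranks for ties.  Returns NaN (an undefined-correlation flag,
    never a silent zero) when either gene has zero variance across spots.
    """
    if section.n_obs < 3:
        raise InputError("spearman_coloc requires at least 3 spots")
    a = _gene_values(section, gene_a)
    b = _gene_values(section, gene_b)
    if a.std() == 0 or b.std() == 0:
        return math.nan
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def genome_screen(
    sections: list[AnnData],
    anchor_gene: str,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    top_fraction: float = 0.25,
    null_mode: str = "values",
    genes: list[str] | None = None,
) -> ScreenResult:
    """Screen every non-anchor gene for consistent proximity to the anchor.

    Per section, each testable gene gets a permutation null and an
    empirical p; empirical p-values are BH-adjusted across genes within
    the section.  A gene is *consistent* iff it was testable (not skipped)
    in every section and its q is at or below alpha in all of them.
    Consistent genes are ranked by mean observed distance ascending, ties
    broken lexicographically.
    """
    if not sections:
        raise InputError("genome_screen requires at least one section")
    per_gene: dict[str, list[ProximityResult]] = {}

    for section in sections:
        sid = section_id(section)
        anchor_mask = high_region_mask(section, anchor_gene, top_fraction)
        if anchor_mask.skipped:
            logger.warning(
                "section %r: anchor mask invalid (%s); section skipped",
                sid, anchor_mask.skip_reason,
            )
            for g in section.var_names:
                if g == anchor_gene:
                    continue
                per_gene.setdefault(str(g), []).append(
                    ProximityResult(
                        str(g), sid, skipped=True,
                        skip_reason=SKIP_ANCHOR_INVALID,
                    )
                )
            continue
        d_field = anchor_distance_field(section, anchor_mask)
        test_genes = [
            str(g)
            for g in (genes if genes is not None else section.var_names)
            if g != anchor_gene
        ]
        section_results: list[ProximityResult] = []
        for g in test_genes:
            res = permutation_null(
                section, anchor_gene, g,
                B=B, seed=seed, top_fraction=top_fraction,
                null_mode=null_mode,
                _anchor_mask=anchor_mask, _d_field=d_field,
            )
            section_results.append(res)
        tested = [r for r in section_results if not r.skipped]
        if tested:
            qs = bh_adjust([r.empirical_p for r in tested])
            for r, q in zip(tested, qs):
                r.q = float(q)
        for r in section_results:
            per_gene.setdefault(r.gene, []).append(r)

    n_sections = len(sections)
    consistent = []
    for g, results in per_gene.items():
        if len(results) != n_sections:
            continue
        if any(r.skipped for r in results):
            continue
        if all(r.q <= alpha for r in results):
            consistent.append(g)
    if not per_gene or not any(
        not r.skipped for rs in per_gene.values() for r in rs
    ):
        logger.warning("genome_screen: no testable genes")

    rows = [
        {
            "gene": g,
            "mean_d_obs": float(np.mean([r.d_obs for r in per_gene[g]])),
            "max_q": float(np.max([r.q for r in per_gene[g]])),
        }
        for g in consistent
    ]
    ranking = pd.DataFrame(rows, columns=["gene", "mean_d_obs", "max_q"])
    if len(ranking):
        ranking = ranking.sort_values(
            ["mean_d_obs", "gene"]
        ).reset_index(drop=True)
        ranking.insert(0, "rank", np.arange(1, len(ranking) + 1))
    else:
        ranking.insert(0, "rank", np.array([], dtype=int))
    consistent_sorted = list(ranking["gene"]) if len(ranking) else []
    return ScreenResult(
        per_gene=per_gene, consistent=consistent_sorted, ranking=ranking
    )


def screen_to_frame(result: ScreenResult) -> pd.DataFrame:
    """Flatten a ScreenResult into one row per (gene, section)."""
    rows = []
    for g, results in sorted(result.per_gene.items()):
        for r in results:
            rows.append(
                {
                    "gene": g,
                    "section_id": r.section_id,
                    "d_obs": r.d_obs,
                    "empirical_p": r.empirical_p,
                    "mwu_p": r.mwu_p,
                    "q": r.q,
                    "skipped": r.skipped,
                    "skip_reason": r.skip_reason or "",
                    "consistent": g in result.consistent,
                }
            )
    return pd.DataFrame(rows)
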