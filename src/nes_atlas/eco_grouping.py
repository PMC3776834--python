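"""Ecological grouping of species from mixed environmental summaries.

Each species is summarised by the mean of the continuous covariates
(altitude, slope, annual rainfall, mean temperature) over its record
locations and the mode of the categorical substrate.  Pairwise Gower
distances (range-normalised absolute differences for continuous variables,
mismatch indicators for the categorical one, averaged over variables) feed
three complementary structure-finding methods: partitioning around medoids,
average-linkage hierarchical clustering, and (non-)metric multidimensional
scaling.  Group number is chosen by silhouette, cross-checked against the
hierarchical cut — when the two disagree, the hierarchical/ordination-
supported number is preferred, since medoid partitions of continuous
gradients can report spurious fine splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score, silhouette_score

from .environment import GEOLOGY_NAMES, EnvLayerStack, extract_at_points

__all__ = [
    "summarize_species_env",
    "gower_matrix",
    "pam_cluster",
    "hierarchical_cluster",
    "classical_mds",
    "nmds_embed",
    "GroupingResult",
    "absorb_small_clusters",
    "partition_isolation",
    "select_groups",
    "run_grouping",
]

CONTINUOUS_VARS = ("elevation", "slope", "rainfall", "temperature")
GEO_TIEBREAK = ("U", "V", "L", "R")


def summarize_species_env(
    records: pd.DataFrame, stack: EnvLayerStack
) -> tuple[pd.DataFrame, dict]:
    """Per-species environmental summary: continuous means + modal substrate.

    Records falling in nodata cells are dropped from the means; species with
    no valid extracted point are excluded and reported in the returned dict.
    """
    table = extract_at_points(stack, records)
    table = table[table["valid"]]
    excluded = sorted(set(records["species_id"]) - set(table["species_id"]))
    rows = []
    for sp, grp in table.groupby("species_id", sort=True):
        row = {"species_id": sp, "n_points": len(grp)}
        for var in CONTINUOUS_VARS:
            row[var] = float(grp[var].mean())
        codes = [GEOLOGY_NAMES.get(v, str(v)) for v in grp["geology"]]
        counts = pd.Series(codes).value_counts()
        top = counts.max()
        modal = min(
            (c for c in counts.index if counts[c] == top),
            key=lambda c: GEO_TIEBREAK.index(c) if c in GEO_TIEBREAK else 99,
        )
        row["geology"] = modal
        rows.append(row)
    report = {"n_species": len(rows), "excluded_no_valid_points": excluded}
    return pd.DataFrame(rows), report


def gower_matrix(summaries: pd.DataFrame) -> np.ndarray:
    """Gower distance matrix over the 4 continuous + 1 categorical summary
    variables.

    Continuous contributions are |a - b| / observed range; the categorical
    contribution is a 0/1 mismatch; the distance is the mean contribution
    over retained variables.  Zero-range continuous variables are dropped
    with a warning; if nothing remains, raises.
    """
    n = len(summaries)
    if n < 2:
        raise ValueError("need at least 2 species")
    contribs = []
    for var in CONTINUOUS_VARS:
        v = summaries[var].to_numpy(dtype=float)
        rng = v.max() - v.min()
        if rng <= 0:
            warnings.warn(f"variable {var!r} has zero range; dropped from the Gower distance")
            continue
        contribs.append(np.abs(v[:, None] - v[None, :]) / rng)
    g = summaries["geology"].to_numpy()
    if len(np.unique(g)) > 1:
        contribs.append((g[:, None] != g[None, :]).astype(float))
    elif not contribs:
        raise ValueError("all variables have zero range; Gower distance undefined")
    else:
        warnings.warn("categorical variable is constant; dropped from the Gower distance")
    d = np.mean(contribs, axis=0)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# Partitioning around medoids (build + swap), on a precomputed distance matrix


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = len(d)
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        # gain of adding candidate j = total reduction in distance-to-nearest
        gains = np.maximum(cur[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return sorted(medoids)


def _pam_cost(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def pam_medoids(d: np.ndarray, k: int, max_iter: int = 200) -> tuple[list[int], np.ndarray]:
    """PAM k-medoids: greedy BUILD then best-improvement SWAP to convergence.

    Deterministic: ties resolve to the smallest index.  Returns (medoids,
    labels); the swap phase never increases the objective.
    """
    n = len(d)
    if not (2 <= k < n):
        raise ValueError("need 2 <= k < n")
    medoids = _pam_build(d, k)
    cost = _pam_cost(d, medoids)
    for _ in range(max_iter):
        dm = d[:, medoids]                      # (n, k)
        order = np.argsort(dm, axis=1)
        d1 = dm[np.arange(n), order[:, 0]]      # nearest-medoid distance
        d2 = dm[np.arange(n), order[:, 1]]      # second nearest
        near = order[:, 0]
        best_delta, best_swap = 0.0, None
        for mi in range(k):
            # distance to nearest medoid once medoid mi is removed
            base = np.where(near == mi, d2, d1)
            # candidate totals for every possible replacement h, vectorised
            totals = np.minimum(base[None, :], d).sum(axis=1)
            totals[medoids] = np.inf
            h = int(np.argmin(totals))
            delta = float(totals[h] - cost)
            if delta < best_delta - 1e-12:
                best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = sorted(medoids)
        cost += best_delta
    labels = np.argmin(d[:, medoids], axis=1)
    return medoids, labels


def classical_mds(d: np.ndarray, dims: int) -> np.ndarray:
    """Classical (Torgerson) scaling of a distance matrix."""
    n = len(d)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    dims = min(dims, n - 1)
    w = np.clip(w[:dims], 0, None)
    return V[:, :dims] * np.sqrt(w)


def _kruskal_stress1(d_obs: np.ndarray, coords: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    dis = squareform(d_obs, checks=False)
    emb = pdist(coords)
    # primary tie handling: tied dissimilarities impose no order, so sort
    # them by the embedded distance (they can never contribute stress)
    order = np.lexsort((emb, dis))
    iso = IsotonicRegression(increasing=True)
    dhat = np.empty_like(emb)
    dhat[order] = iso.fit_transform(np.arange(len(dis)), emb[order])
    denom = float((emb**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((emb - dhat) ** 2).sum() / denom))


def nmds_embed(
    d: np.ndarray, dims: int = 2, seed: int = 0, n_restarts: int = 8, max_iter: int = 300
) -> tuple[np.ndarray, float]:
    """Non-metric MDS by SMACOF with monotone regression (Kruskal stress-1).

    Runs from a classical-scaling start plus ``n_restarts`` seeded random
    starts and keeps the configuration with the lowest stress-1.
    """
    from sklearn.manifold import smacof

    if dims < 1:
        raise ValueError("dims must be >= 1")
    rng = np.random.default_rng(seed)
    inits = [classical_mds(d, dims)]
    if inits[0].shape[1] < dims:  # pad if n-1 < dims
        pad = np.zeros((len(d), dims - inits[0].shape[1]))
        inits[0] = np.hstack([inits[0], pad])
    for _ in range(n_restarts):
        inits.append(rng.normal(scale=d.mean() + 1e-12, size=(len(d), dims)))
    best: tuple[float, np.ndarray] | None = None
    for init in inits:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, _ = smacof(
                d, metric=False, n_components=dims, init=init, n_init=1,
                max_iter=max_iter, eps=1e-9, normalized_stress=False,
            )
        s1 = _kruskal_stress1(d, coords)
        if best is None or s1 < best[0]:
            best = (s1, coords)
    return best[1], best[0]


def hierarchical_cluster(d: np.ndarray, method: str = "average") -> np.ndarray:
    """Average-linkage (UPGMA) tree as a SciPy linkage matrix."""
    if len(d) < 2:
        raise ValueError("need at least 2 items")
    return linkage(squareform(d, checks=False), method=method)


def cophenetic_distances(tree: np.ndarray) -> np.ndarray:
    return squareform(cophenet(tree))


def pam_cluster(d: np.ndarray, k_range=range(2, 9), embed_dims: int | None = None) -> dict:
    """PAM over a range of k with validity indices.

    Silhouette is computed directly on the distance matrix; the
    Calinski-Harabasz index needs coordinates, so it is computed on a
    classical-scaling embedding of the distances (dimension
    ``min(n - 1, 10)`` by default).
    """
    n = len(d)
    results = {}
    dims = embed_dims or min(n - 1, 10)
    coords = classical_mds(d, dims)
    for k in k_range:
        if k >= n:
            raise ValueError(f"k={k} >= n={n}")
        medoids, labels = pam_medoids(d, k)
        sil = float(silhouette_score(d, labels, metric="precomputed"))
        ch = float(calinski_harabasz_score(coords, labels))
        results[k] = {"medoids": medoids, "labels": labels, "silhouette": sil,
                      "calinski_harabasz": ch}
    return results


@dataclass
class GroupingResult:
    """Everything the group search produced, plus the final choice."""

    distance: np.ndarray
    pam: dict
    tree: np.ndarray
    nmds_coords: np.ndarray
    nmds_stress: float
    chosen_k: int
    labels: np.ndarray
    agreement_ari: float
    disagreement_note: str = ""
    summaries: pd.DataFrame | None = None


def absorb_small_clusters(d: np.ndarray, labels: np.ndarray, min_size: int = 3) -> np.ndarray:
    """Merge clusters smaller than ``min_size`` into their nearest (by
    average distance) cluster — the formal stand-in for ignoring stragglers
    when judging a cluster plot by eye."""
    labels = np.asarray(labels).copy()
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) <= 1:
            break
        small = uniq[counts < min_size]
        if len(small) == 0:
            break
        g = small[0]
        idx = labels == g
        best, bestd = None, np.inf
        for h in uniq:
            if h == g:
                continue
            dd = d[np.ix_(idx, labels == h)].mean()
            if dd < bestd:
                bestd, best = dd, h
        labels[idx] = best
    return labels


def partition_isolation(d: np.ndarray, labels: np.ndarray) -> float:
    """Smallest single-linkage gap between any two clusters, in units of the
    median nearest-neighbour distance.

    A partition that cuts a continuous gradient has a between-cluster gap of
    about one nearest-neighbour spacing (ratio near 1); clusters separated
    by a real discontinuity score much higher.
    """
    n = len(d)
    offdiag = d + np.diag(np.full(n, np.inf))
    nn = np.median(offdiag.min(axis=1))
    uniq = np.unique(labels)
    gap = np.inf
    for i, a in enumerate(uniq):
        ai = labels == a
        for b in uniq[i + 1 :]:
            gap = min(gap, float(d[np.ix_(ai, labels == b)].min()))
    return gap / max(nn, 1e-12)


def select_groups(
    d: np.ndarray,
    pam_results: dict,
    tree: np.ndarray,
    ari_threshold: float = 0.7,
    isolation_factor: float = 4.0,
    min_group_size: int = 3,
) -> tuple[int, np.ndarray, float, str]:
    """Choose the number of groups from the PAM partitions and tree cuts.

    Candidate partitions are the PAM result and the average-linkage cut at
    every k (small clusters absorbed).  Candidates whose clusters are not
    mutually isolated — some between-cluster single-linkage gap below
    ``isolation_factor`` nearest-neighbour spacings — are discarded: a
    medoid partition happily slices a continuous gradient, and such slices
    show no discontinuity in the tree or the ordination.  Among admissible
    partitions the mean silhouette decides.  Returns (k, labels,
    pam_tree_ari, note); the note records an override of the silhouette-
    maximal PAM k, and ``pam_tree_ari`` is the agreement between the PAM
    partition and the tree cut at the chosen k.
    """
    from sklearn.metrics import silhouette_score

    candidates: list[tuple[str, int, np.ndarray]] = []
    # connectivity cuts: a mixed-variable cloud is a connected gradient within
    # a group but steps discontinuously across the categorical boundary, so
    # single-linkage components are the natural candidates for isolated groups
    con_tree = linkage(squareform(d, checks=False), method="single")
    for k, res in pam_results.items():
        candidates.append(("pam", k, absorb_small_clusters(d, res["labels"], min_group_size)))
        cut = fcluster(tree, t=k, criterion="maxclust") - 1
        candidates.append(("tree", k, absorb_small_clusters(d, cut, min_group_size)))
        ccut = fcluster(con_tree, t=k, criterion="maxclust") - 1
        candidates.append(("connectivity", k, absorb_small_clusters(d, ccut, min_group_size)))
    scored = []
    for src, k, lab in candidates:
        if len(np.unique(lab)) < 2:
            continue
        sil = float(silhouette_score(d, lab, metric="precomputed"))
        iso = partition_isolation(d, lab)
        scored.append({"source": src, "cut_k": k, "labels": lab, "silhouette": sil,
                       "isolation": iso, "k": int(len(np.unique(lab)))})
    if not scored:
        raise ValueError("no admissible partition with at least 2 groups")
    admissible = [s for s in scored if s["isolation"] >= isolation_factor]
    if admissible:
        # the finest partition whose groups are all genuinely isolated —
        # the formal counterpart of counting the distinguishable clusters
        # in the ordination; silhouette breaks ties
        best = max(admissible, key=lambda s: (s["k"], s["silhouette"]))
    else:
        best = max(scored, key=lambda s: (s["silhouette"], -s["k"]))
    sil_k = max(pam_results, key=lambda k: (pam_results[k]["silhouette"], -k))
    note = ""
    if best["k"] != sil_k or best["source"] != "pam":
        note = (
            f"silhouette-maximal PAM k={sil_k} overridden: chosen partition is the "
            f"{best['source']} cut at k={best['cut_k']} ({best['k']} groups after "
            f"absorbing stragglers), isolation {best['isolation']:.1f} nn-spacings"
        )
    if not admissible:
        note = (note + "; " if note else "") + "no partition met the isolation bar; best silhouette kept"
    labels = best["labels"]
    ari = float(
        adjusted_rand_score(labels, fcluster(tree, t=best["k"], criterion="maxclust"))
    )
    return best["k"], labels, ari, note


def run_grouping(
    summaries: pd.DataFrame,
    k_range=range(2, 9),
    seed: int = 0,
    ari_threshold: float = 0.7,
    subgroup_search: bool = True,
) -> GroupingResult:
    """Full grouping pipeline: Gower -> PAM + UPGMA + NMDS -> group choice.

    With ``subgroup_search`` the chosen groups are re-clustered separately
    and the per-group maximal silhouettes recorded (weak values mean no
    further substructure), mirroring a recursive search for subgroups.
    Fewer than 3 species: grouping is skipped (chosen_k 1).
    """
    n = len(summaries)
    d = gower_matrix(summaries)
    if n < 3:
        return GroupingResult(
            distance=d, pam={}, tree=np.empty((0, 4)), nmds_coords=np.zeros((n, 2)),
            nmds_stress=0.0, chosen_k=1, labels=np.zeros(n, dtype=int),
            agreement_ari=1.0, disagreement_note="too few species; grouping skipped",
            summaries=summaries,
        )
    k_range = [k for k in k_range if k < n]
    pam_results = pam_cluster(d, k_range)
    tree = hierarchical_cluster(d)
    coords, stress = nmds_embed(d, dims=2, seed=seed)
    k, labels, ari, note = select_groups(d, pam_results, tree, ari_threshold)
    result = GroupingResult(
        distance=d, pam=pam_results, tree=tree, nmds_coords=coords, nmds_stress=stress,
        chosen_k=k, labels=np.asarray(labels), agreement_ari=ari, disagreement_note=note,
        summaries=summaries,
    )
    if subgroup_search:
        sub = {}
        for g in np.unique(result.labels):
            idx = np.nonzero(result.labels == g)[0]
            if len(idx) < 6:
                continue
            dg = d[np.ix_(idx, idx)]
            subres = pam_cluster(dg, [kk for kk in (2, 3, 4) if kk < len(idx)])
            sub[int(g)] = max(r["silhouette"] for r in subres.values())
        result.subgroup_silhouette = sub  # type: ignore[attr-defined]
    return result
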