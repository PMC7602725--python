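"""Between-sample and between-population structure.

* **IBS distances** — per SNP pair of samples, the number of shared alleles
  is ``2 - |d_i - d_j| - [both het]`` (identical homozygotes share 2,
  hom/het share 1, het/het share 1, opposite homozygotes share 0); the
  distance is one minus the shared-allele fraction over jointly called SNPs.
  This matches PLINK's ``1 - DST`` when het/het is scored as one shared
  allele pair.
* **Classical MDS** — Torgerson double-centering of squared distances and
  eigendecomposition; axis signs fixed so each axis' largest-magnitude
  loading is positive.
* **F_ST** — the Hudson-type estimator per SNP with ratio-of-averages
  aggregation (the eigensoft convention); Weir–Cockerham offered as an
  option.
* **Neighbor joining** — Saitou–Nei with the standard Q criterion,
  deterministic lexicographic tie-breaking, Newick output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Square symmetric distance matrix with ordered labels."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class MDSResult:
    """Low-dimensional embedding: ``coordinates`` is samples x k, axes ordered
    by non-increasing eigenvalue."""

    ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray

    def to_frame(self, populations: dict[str, str] | None = None) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        out = pd.DataFrame(
            self.coordinates, columns=[f"c{i + 1}" for i in range(k)]
        )
        out.insert(0, "sample_id", self.ids)
        if populations:
            out.insert(1, "population", [populations[s] for s in self.ids])
        return out


@dataclass
class FstMatrix:
    populations: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations, columns=self.populations)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    def clamped(self) -> "FstMatrix":
        """Copy with negative estimates clamped to 0 (for tree building)."""
        return FstMatrix(self.populations, np.maximum(self.values, 0.0))


@dataclass
class NJTree:
    """Unrooted neighbor-joining tree over population labels."""

    newick: str
    leaf_labels: list[str]


# ---------------------------------------------------------------------------
# IBS distances
# ---------------------------------------------------------------------------

def ibs_distance_matrix(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise identity-by-state distances between samples.

    Uses only jointly non-missing SNPs per pair; raises if some pair shares
    no called SNP.  Restrict to autosomes beforehand (``g.restrict_chroms``)
    when sex chromosomes are present.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    called = g.calls != MISSING
    het = (g.calls == 1).astype(np.float64)
    M = called.astype(np.float64)

    # |d_i - d_j| summed over shared SNPs, via indicators of each dosage level
    level = [((g.calls == k) & called).astype(np.float64) for k in (0, 1, 2)]
    absdiff = np.zeros((g.n_samples, g.n_samples))
    for a in range(3):
        for b in range(3):
            if a != b:
                absdiff += abs(a - b) * level[a] @ level[b].T
    both_het = het @ het.T
    n_shared = M @ M.T
    if np.any(n_shared[~np.eye(g.n_samples, dtype=bool)] == 0):
        i, j = np.argwhere((n_shared == 0) & ~np.eye(g.n_samples, dtype=bool))[0]
        raise ValueError(
            f"samples {g.samples[i].sample_id} and {g.samples[j].sample_id} "
            "share no called SNP"
        )
    shared_alleles = 2.0 * n_shared - absdiff - both_het
    similarity = shared_alleles / (2.0 * n_shared)
    d = 1.0 - similarity
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry
    return DistanceMatrix(ids=list(g.sample_ids), d=d)


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------

def classical_mds(dist: DistanceMatrix, k: int = 2) -> MDSResult:
    """Torgerson/Gower classical multidimensional scaling into ``k`` axes.

    Coordinates are the top-``k`` eigenvectors of the double-centered squared
    distance matrix, scaled by the square roots of their eigenvalues.  If
    fewer than ``k`` eigenvalues are positive the embedding is truncated with
    a warning.  Deterministic up to axis sign, which is fixed by making each
    axis' largest-magnitude coordinate positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = dist.d
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-12).sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} axes",
            stacklevel=2,
        )
        k = max(n_pos, 1)
    lam = np.maximum(evals[:k], 0.0)
    coords = evecs[:, :k] * np.sqrt(lam)
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return MDSResult(ids=list(dist.ids), coordinates=coords, eigenvalues=evals[:k])


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _pop_stats(g: GenotypeMatrix, rows: np.ndarray):
    """Per-SNP allele2 frequency, allele count (2 x called), individual count
    and heterozygote proportion for a sample subset."""
    sub = g.calls[rows, :]
    called = sub != MISSING
    n_ind = called.sum(axis=0).astype(float)
    n_alleles = 2.0 * n_ind
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called, sub, 0).sum(axis=0) / np.where(n_alleles > 0, n_alleles, 1)
        het = (sub == 1).sum(axis=0) / np.where(n_ind > 0, n_ind, 1)
    return freq.astype(float), n_alleles, n_ind, het.astype(float)


def _hudson_components(s1, s2) -> tuple[np.ndarray, np.ndarray]:
    p1, n1, _, _ = s1
    p2, n2, _, _ = s2
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
        - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _wc_components(s1, s2) -> tuple[np.ndarray, np.ndarray]:
    # Weir-Cockerham (1984) theta, two populations, diploid genotype data
    p1, _, n1, h1 = s1
    p2, _, n2, h2 = s2
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    ssq = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        ssq
        - (pbar * (1 - pbar) - (r - 1) / r * ssq - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * ssq
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, a + b + c


def hudson_fst_matrix(
    g: GenotypeMatrix,
    labels: dict[str, str] | None = None,
    estimator: str = "hudson",
) -> FstMatrix:
    """Pairwise F_ST between populations, ratio-of-averages over SNPs.

    SNPs monomorphic across both populations of a pair are skipped.  The
    default Hudson estimator is the eigensoft convention; ``"wc"`` selects
    Weir–Cockerham.  Estimates can be slightly negative; use
    :meth:`FstMatrix.clamped` before tree building.
    """
    if estimator not in ("hudson", "wc"):
        raise ValueError(f"unknown estimator {estimator!r}")
    labels = labels or g.population_map()
    pops_of = np.array([labels[s] for s in g.sample_ids])
    pop_names = sorted(set(pops_of))
    if len(pop_names) < 2:
        raise ValueError("need at least 2 populations")
    rows = {p: np.flatnonzero(pops_of == p) for p in pop_names}
    for p, r in rows.items():
        if r.size < 2:
            raise ValueError(f"population {p} has fewer than 2 samples")
    stats = {p: _pop_stats(g, r) for p, r in rows.items()}

    k = len(pop_names)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            s1 = stats[pop_names[i]]
            s2 = stats[pop_names[j]]
            p1, n1 = s1[0], s1[1]
            p2, n2 = s2[0], s2[1]
            ok = (n1 >= 4) & (n2 >= 4)  # at least 2 diploid samples called
            # drop SNPs monomorphic across the pair
            poly = ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
            ok &= poly
            if not ok.any():
                raise ValueError(
                    f"no polymorphic SNP between {pop_names[i]} and {pop_names[j]}"
                )
            comp = _hudson_components if estimator == "hudson" else _wc_components
            num, den = comp(
                tuple(x[ok] for x in s1), tuple(x[ok] for x in s2)
            )
            out[i, j] = out[j, i] = float(num.sum() / den.sum())
    return FstMatrix(populations=pop_names, values=out)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _fmt_branch(x: float) -> str:
    return f"{x:.10g}"


_NWK_SPECIAL = set("();:,[]' \t\n")


def _nwk_label(label: str) -> str:
    """Quote a leaf label when it contains Newick metacharacters."""
    if any(ch in _NWK_SPECIAL for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def neighbor_joining_tree(
    dist: FstMatrix | DistanceMatrix, clamp_negative_input: bool = True
) -> NJTree:
    """Saitou–Nei neighbor joining over a population distance matrix.

    Accepts an :class:`FstMatrix` (negative entries clamped to 0 by default)
    or any :class:`DistanceMatrix`.  Ties in the Q criterion are broken by
    the lexicographically smallest label pair, making the output independent
    of taxon input order.  Returns an unrooted Newick tree (trifurcating
    root) with branch lengths.
    """
    if isinstance(dist, FstMatrix):
        labels = list(dist.populations)
        d0 = np.array(dist.values, dtype=float)
    else:
        labels = list(dist.ids)
        d0 = np.array(dist.d, dtype=float)
    if clamp_negative_input:
        d0 = np.maximum(d0, 0.0)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(d0)):
        raise ValueError("distances must be finite")

    # canonical input order: sort taxa lexicographically
    order = sorted(range(n), key=lambda i: labels[i])
    labels = [labels[i] for i in order]
    d = d0[np.ix_(order, order)]

    # active nodes: sort_key -> (newick fragment, row index)
    keys = list(labels)
    newicks = [_nwk_label(x) for x in labels]

    while len(keys) > 3:
        m = len(keys)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        frag = f"({newicks[i]}:{_fmt_branch(li)},{newicks[j]}:{_fmt_branch(lj)})"
        key = min(keys[i], keys[j])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d_next = np.zeros((len(keep) + 1, len(keep) + 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = dnew[keep]
        d = d_next
        keys = [keys[x] for x in keep] + [key]
        newicks = [newicks[x] for x in keep] + [frag]

    # join the final three nodes at a central trifurcation
    (a, b, c) = (0, 1, 2)
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    newick = (
        f"({newicks[a]}:{_fmt_branch(la)},{newicks[b]}:{_fmt_branch(lb)},"
        f"{newicks[c]}:{_fmt_branch(lc)});"
    )
    return NJTree(newick=newick, leaf_labels=sorted(labels))
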