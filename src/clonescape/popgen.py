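"""F-statistics and matrix association tests for site-level structure.

Differentiation among sites is measured with the Weir & Cockerham (1984)
estimator theta of F_ST, computed from the a/b/c variance components
(among-site, among-genet-within-site, within-genet) summed over alleles and
loci: ``theta = sum(a) / sum(a + b + c)``. Analyses use unique genets only.
Significance of pairwise theta comes from permuting genets between the two
sites. Isolation by distance and flow-based alternatives are tested by
Mantel correlation of ``F_ST/(1-F_ST)`` against distance or dispersal
matrices with one-tailed permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genotypes import ClonalPartition, MultilocusGenotype
from .matrices import LabelledMatrix

__all__ = [
    "FstResult",
    "PairwiseFstResult",
    "wc_fst",
    "pairwise_fst_matrix",
    "linearize_fst",
    "mantel",
    "genets_by_site",
]


@dataclass
class FstResult:
    theta: float
    per_locus: list
    components: list  # per-locus (a, b, c) sums over alleles
    p_value: float | None = None
    n_perm: int = 0


@dataclass
class PairwiseFstResult:
    theta: LabelledMatrix
    p_values: LabelledMatrix | None
    significant: np.ndarray | None  # boolean, aligned with theta.labels
    alpha_adjusted: float | None
    n_perm: int = 0

    @property
    def n_pairs(self) -> int:
        n = self.theta.n
        return n * (n - 1) // 2


def genets_by_site(
    partitions: Mapping[str, ClonalPartition],
) -> "dict[str, list[MultilocusGenotype]]":
    """Unique genets per site, ready for F-statistics."""
    return {s: p.representative_mlgs() for s, p in partitions.items()}


# ---------------------------------------------------------------------------
# encoding: per locus, integer allele codes per genet plus site codes


def _encode(sites_genotypes: Mapping[str, Sequence[MultilocusGenotype]]):
    site_names = list(sites_genotypes)
    genets = []
    site_codes = []
    for i, s in enumerate(site_names):
        gs = list(sites_genotypes[s])
        if len(gs) < 2:
            raise ValueError(f"site {s!r} has fewer than 2 genets")
        genets.extend(gs)
        site_codes.extend([i] * len(gs))
    n_loci = genets[0].n_loci
    site_codes = np.asarray(site_codes)
    loci = []
    for loc in range(n_loci):
        codes: dict[int, int] = {}
        a1 = np.full(len(genets), -1)
        a2 = np.full(len(genets), -1)
        for g_i, g in enumerate(genets):
            c = g.calls[loc]
            if c is None:
                continue
            a1[g_i] = codes.setdefault(c[0], len(codes))
            a2[g_i] = codes.setdefault(c[1], len(codes))
        loci.append((a1, a2, len(codes)))
    return site_names, site_codes, loci


def _locus_onehot(a1, a2, k):
    """Per-genet allele-copy counts X (n,k), heterozygote-carrier flags H (n,k)."""
    n = len(a1)
    X = np.zeros((n, k))
    H = np.zeros((n, k))
    called = a1 >= 0
    idx = np.nonzero(called)[0]
    np.add.at(X, (idx, a1[idx]), 1.0)
    np.add.at(X, (idx, a2[idx]), 1.0)
    het = called & (a1 != a2)
    hidx = np.nonzero(het)[0]
    H[hidx, a1[hidx]] = 1.0
    H[hidx, a2[hidx]] = 1.0
    return X, H, called.astype(float)


def _locus_components(n_i, p_i, h_i):
    """Weir-Cockerham a, b, c summed over alleles for one locus.

    n_i: (r,) genets called per site; p_i: (r,k) allele frequencies;
    h_i: (r,k) heterozygote-carrier frequencies.
    """
    r = len(n_i)
    N = n_i.sum()
    nbar = N / r
    if r < 2 or nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (N - (n_i**2).sum() / N) / (r - 1)
    pbar = (n_i[:, None] * p_i).sum(0) / N
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_i).sum(0) / N
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def _theta_components(site_codes, loci, r):
    comps = []
    for a1, a2, k in loci:
        if k == 0:
            comps.append((0.0, 0.0, 0.0))
            continue
        X, H, called = _locus_onehot(a1, a2, k)
        n_i = np.zeros(r)
        np.add.at(n_i, site_codes, called)
        keep = n_i > 0
        if keep.sum() < 2:
            comps.append((0.0, 0.0, 0.0))
            continue
        C = np.zeros((r, k))
        Hc = np.zeros((r, k))
        np.add.at(C, site_codes, X * called[:, None])
        np.add.at(Hc, site_codes, H * called[:, None])
        n_k = n_i[keep]
        p_i = C[keep] / (2 * n_k[:, None])
        h_i = Hc[keep] / n_k[:, None]
        comps.append(_locus_components(n_k, p_i, h_i))
    return comps


def wc_fst(
    sites_genotypes: Mapping[str, Sequence[MultilocusGenotype]],
    n_perm: int = 0,
    seed: int | None = None,
) -> FstResult:
    """Multilocus Weir-Cockerham theta over >= 2 sites of unique genets.

    Loci with no variation contribute zero components. With ``n_perm > 0`` a
    permutation p-value is computed by shuffling genets among sites.
    """
    site_names, site_codes, loci = _encode(sites_genotypes)
    r = len(site_names)
    if r < 2:
        raise ValueError("need at least two sites")
    comps = _theta_components(site_codes, loci, r)
    A = sum(c[0] for c in comps)
    D = sum(sum(c) for c in comps)
    theta = A / D if D != 0 else 0.0
    per_locus = [
        (c[0] / (c[0] + c[1] + c[2])) if (c[0] + c[1] + c[2]) != 0 else np.nan
        for c in comps
    ]
    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(site_codes)
            pc = _theta_components(perm, loci, r)
            pA = sum(c[0] for c in pc)
            pD = sum(sum(c) for c in pc)
            if (pA / pD if pD != 0 else 0.0) >= theta:
                hits += 1
        p_value = (1 + hits) / (n_perm + 1)
    return FstResult(
        theta=float(theta),
        per_locus=per_locus,
        components=comps,
        p_value=p_value,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# pairwise theta with vectorized permutations


def _pair_theta_perms(g1, g2, n_perm, rng):
    """theta for the observed pair plus ``n_perm`` genet-label permutations.

    Returns an array of length n_perm + 1; entry 0 is the observed theta.
    All permutations are evaluated in one vectorized pass per locus.
    """
    genets = list(g1) + list(g2)
    n, n1 = len(genets), len(g1)
    B = n_perm + 1
    M = np.zeros((B, n))
    M[0, :n1] = 1.0
    for b in range(1, B):
        M[b, rng.permutation(n)[:n1]] = 1.0
    n_loci = genets[0].n_loci
    A_sum = np.zeros(B)
    D_sum = np.zeros(B)
    for loc in range(n_loci):
        codes: dict[int, int] = {}
        a1 = np.full(n, -1)
        a2 = np.full(n, -1)
        for i, g in enumerate(genets):
            c = g.calls[loc]
            if c is None:
                continue
            a1[i] = codes.setdefault(c[0], len(codes))
            a2[i] = codes.setdefault(c[1], len(codes))
        k = len(codes)
        if k == 0:
            continue
        X, H, called = _locus_onehot(a1, a2, k)
        Xc = X * called[:, None]
        Hc = H * called[:, None]
        tot_n = called.sum()
        totC = Xc.sum(0)
        totH = Hc.sum(0)
        n0 = M @ called
        n1v = tot_n - n0
        ok = (n0 > 0) & (n1v > 0) & ((n0 + n1v) / 2 > 1)
        C0 = M @ Xc
        C1 = totC - C0
        H0 = M @ Hc
        H1 = totH - H0
        with np.errstate(divide="ignore", invalid="ignore"):
            p0 = C0 / (2 * n0[:, None])
            p1 = C1 / (2 * n1v[:, None])
            h0 = H0 / n0[:, None]
            h1 = H1 / n1v[:, None]
            N = n0 + n1v
            nbar = N / 2
            nc = (N - (n0**2 + n1v**2) / N)  # r - 1 = 1
            pbar = (C0 + C1) / (2 * N[:, None])
            s2 = (
                n0[:, None] * (p0 - pbar) ** 2 + n1v[:, None] * (p1 - pbar) ** 2
            ) / nbar[:, None]
            hbar = (H0 + H1) / N[:, None]
            inner = pbar * (1 - pbar) - s2 / 2
            a = (nbar / nc)[:, None] * (
                s2 - (inner - hbar / 4) / (nbar - 1)[:, None]
            )
            b_ = (nbar / (nbar - 1))[:, None] * (
                inner - ((2 * nbar - 1) / (4 * nbar))[:, None] * hbar
            )
            c_ = hbar / 2
            la = np.where(ok[:, None], a, 0.0).sum(1)
            ld = np.where(ok[:, None], a + b_ + c_, 0.0).sum(1)
        A_sum += la
        D_sum += ld
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(D_sum != 0, A_sum / D_sum, 0.0)
    return theta


def pairwise_fst_matrix(
    sites_genotypes: Mapping[str, Sequence[MultilocusGenotype]],
    n_perm: int = 2499,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PairwiseFstResult:
    """Pairwise theta for every unordered site pair, with permutation p-values.

    p-values come from permuting genets between the pair; the significance
    mask applies a Bonferroni-adjusted alpha (``alpha / n_pairs``; 0.05/120
    is approximately 0.0004 for 16 sites). Diagonal is zero.
    """
    names = list(sites_genotypes)
    k = len(names)
    if k < 2:
        raise ValueError("need at least two sites")
    rng = np.random.default_rng(seed)
    theta = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            if n_perm > 0:
                thetas = _pair_theta_perms(
                    sites_genotypes[names[i]], sites_genotypes[names[j]], n_perm, rng
                )
                theta[i, j] = theta[j, i] = thetas[0]
                p = (1 + np.sum(thetas[1:] >= thetas[0])) / (n_perm + 1)
                pvals[i, j] = pvals[j, i] = p
            else:
                res = wc_fst(
                    {
                        names[i]: sites_genotypes[names[i]],
                        names[j]: sites_genotypes[names[j]],
                    }
                )
                theta[i, j] = theta[j, i] = res.theta
    theta_m = LabelledMatrix(labels=tuple(names), values=theta, kind="symmetric")
    if n_perm > 0:
        n_pairs = k * (k - 1) // 2
        alpha_adj = alpha / n_pairs
        np.fill_diagonal(pvals, np.nan)
        p_m = LabelledMatrix(labels=tuple(names), values=pvals, kind="symmetric")
        sig = pvals < alpha_adj
        return PairwiseFstResult(theta_m, p_m, sig, alpha_adj, n_perm)
    return PairwiseFstResult(theta_m, None, None, None, 0)


def linearize_fst(matrix: LabelledMatrix) -> LabelledMatrix:
    """Elementwise F_ST / (1 - F_ST), the linearized differentiation used for IBD."""
    if np.any(matrix.values >= 1.0):
        raise ValueError("entries must be < 1 to linearize")
    return matrix.map(lambda v: v / (1.0 - v))


def mantel(
    A: LabelledMatrix,
    B: LabelledMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    log_transform: bool = False,
    alternative: str = "greater",
) -> tuple[float, float, float]:
    """Mantel correlation between two symmetric labelled matrices.

    Pearson r over the strict upper triangles; one-tailed p-value from
    jointly permuting rows and columns of ``B``. ``log_transform`` takes the
    natural log of the off-diagonal entries of both matrices (all must be
    strictly positive). Returns ``(r, r_squared, p)``.
    """
    if A.labels != B.labels:
        raise ValueError("matrices must share identical labels")
    if A.kind != "symmetric" or B.kind != "symmetric":
        raise ValueError("mantel requires symmetric matrices")
    n = A.n
    if n < 3:
        raise ValueError("need at least 3 labels")
    a = A.values.copy()
    b = B.values.copy()
    iu = np.triu_indices(n, k=1)
    if log_transform:
        for name, m in (("A", a), ("B", b)):
            bad = [
                (A.labels[i], A.labels[j])
                for i, j in zip(*iu)
                if m[i, j] <= 0
            ]
            if bad:
                raise ValueError(f"{name}: non-positive entries under log: {bad}")
        a[iu] = np.log(a[iu])
        a.T[iu] = a[iu]
        b[iu] = np.log(b[iu])
        b.T[iu] = b[iu]
    x = a[iu]
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    # batch-permute B: (n_perm, n, n) then extract triangles
    bp = b[perms[:, :, None], perms[:, None, :]]
    ys = np.concatenate([b[iu][None, :], bp[:, iu[0], iu[1]]], axis=0)
    xc = x - x.mean()
    yc = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum()) * np.sqrt((yc**2).sum(axis=1))
    if denom[0] == 0:
        raise ValueError("zero variance in matrix entries")
    rs = (yc @ xc) / denom
    r = float(rs[0])
    if alternative == "greater":
        hits = np.sum(rs[1:] >= r)
    elif alternative == "less":
        hits = np.sum(rs[1:] <= r)
    else:
        hits = np.sum(np.abs(rs[1:]) >= abs(r))
    p = float((1 + hits) / (n_perm + 1))
    return r, r * r, p
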