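"""Nei–Gojobori (1986) synonymous/nonsynonymous substitution analysis with
Jukes–Cantor correction and a codon-bootstrap Z-test for positive selection.

The method counts, for each codon, fractional synonymous and nonsynonymous
*sites* (how many of the nine one-step nucleotide changes preserve the
encoded amino acid, mutations to stop codons excluded from the denominator)
and, for each pair of differing codons, synonymous and nonsynonymous
*differences* averaged with equal weight over all minimal substitution
pathways that avoid stop codons.  Proportions pS = Sd/S and pN = Nd/N are
distance-corrected with the Jukes–Cantor formula

    d = -(3/4) * ln(1 - (4/3) p),

undefined for p >= 3/4.  Positive selection is tested by Z = (dN - dS)/SE
with the SE of (dN - dS) estimated by bootstrap over codon positions, and a
one-sided normal p-value against the strictly neutral null dN = dS.

Analyses can be partitioned by codon class (all sites, antigen-binding
sites, non-ABS) via a :class:`~mhcds.io_formats.SiteList` mask.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io_formats import AlleleCatalog, SiteList

__all__ = [
    "GENETIC_CODE",
    "SENSE_CODONS",
    "translate_codon",
    "ng86_site_counts",
    "ng86_codon_pair_diffs",
    "ng86_pairwise",
    "jukes_cantor",
    "selection_z_test",
    "SelectionResult",
]

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
GENETIC_CODE: dict[str, str] = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c, aa in sorted(GENETIC_CODE.items()) if aa != "*"
)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon]


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of a sense codon.

    Each position contributes syn/(3 - stops) synonymous sites, where the
    three alternative bases are classified as synonymous, nonsynonymous or
    stop-creating; the two fractions always sum to 3.
    """
    aa = GENETIC_CODE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site counts")
    syn_total = 0.0
    for pos in range(3):
        syn = stops = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            mut_aa = GENETIC_CODE[mut]
            if mut_aa == "*":
                stops += 1
            elif mut_aa == aa:
                syn += 1
        denom = 3 - stops
        if denom > 0:
            syn_total += syn / denom
    return syn_total, 3.0 - syn_total


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over stop-free minimal
    substitution pathways between two sense codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff):
        cur = c1
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            totals.append((syn, non))
    if not totals:
        # all pathways blocked by stops (cannot occur between sense codons
        # differing at <=1 position; vanishingly rare otherwise) -- fall
        # back to averaging over all pathways, counting stop steps as
        # nonsynonymous.
        for order in itertools.permutations(diff):
            cur = c1
            syn = non = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if GENETIC_CODE[nxt] != "*" and GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                    syn += 1
                else:
                    non += 1
                cur = nxt
            totals.append((syn, non))
    s = sum(t[0] for t in totals) / len(totals)
    n = sum(t[1] for t in totals) / len(totals)
    return s, n


@lru_cache(maxsize=1)
def _pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precomputed per-sense-codon site counts and per-codon-pair pathway-
    averaged difference counts (61, 61x61 arrays)."""
    n = len(SENSE_CODONS)
    syn_sites = np.empty(n)
    non_sites = np.empty(n)
    for i, c in enumerate(SENSE_CODONS):
        syn_sites[i], non_sites[i] = ng86_site_counts(c)
    sd = np.zeros((n, n))
    nd = np.zeros((n, n))
    for i, c1 in enumerate(SENSE_CODONS):
        for j in range(i + 1, n):
            s, d = _pathway_counts(c1, SENSE_CODONS[j])
            sd[i, j] = sd[j, i] = s
            nd[i, j] = nd[j, i] = d
    return syn_sites, non_sites, sd, nd


def ng86_codon_pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon pair."""
    return _pathway_counts(c1, c2)


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction; NaN when p >= 3/4."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - (4.0 / 3.0) * p)


def _codon_indices(seq: str) -> np.ndarray:
    """Map an aligned sequence to sense-codon indices; -1 for codons that
    contain a gap (or, defensively, a terminal stop)."""
    n_codons = len(seq) // 3
    out = np.full(n_codons, -1, dtype=np.int64)
    for k in range(n_codons):
        codon = seq[3 * k : 3 * k + 3]
        out[k] = _CODON_INDEX.get(codon, -1)
    return out


def ng86_pairwise(
    seq1: str, seq2: str, site_mask: np.ndarray | None = None
) -> dict[str, float]:
    """NG86 proportions and JC-corrected distances for one sequence pair.

    Codons with a gap (or unrecognized state) in either sequence are dropped
    pairwise.  ``site_mask`` is a boolean per-codon mask restricting the
    analysis to a site class.
    """
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("sequences must be equal-length and in frame")
    syn_sites, non_sites, sd_tab, nd_tab = _pair_tables()
    i1 = _codon_indices(seq1)
    i2 = _codon_indices(seq2)
    valid = (i1 >= 0) & (i2 >= 0)
    if site_mask is not None:
        valid &= np.asarray(site_mask, dtype=bool)
    a, b = i1[valid], i2[valid]
    S = 0.5 * (syn_sites[a].sum() + syn_sites[b].sum())
    N = 0.5 * (non_sites[a].sum() + non_sites[b].sum())
    Sd = sd_tab[a, b].sum()
    Nd = nd_tab[a, b].sum()
    pS = Sd / S if S > 0 else float("nan")
    pN = Nd / N if N > 0 else float("nan")
    return {
        "S": S,
        "N": N,
        "Sd": Sd,
        "Nd": Nd,
        "pS": pS,
        "pN": pN,
        "dS": jukes_cantor(pS) if np.isfinite(pS) else float("nan"),
        "dN": jukes_cantor(pN) if np.isfinite(pN) else float("nan"),
    }


@dataclass
class SelectionResult:
    partition: str
    dN: float
    dS: float
    omega: float
    z: float
    p_value: float
    n_boot: int
    seed: int
    n_codons: int
    n_alleles: int


def _per_pair_per_codon(catalog: AlleleCatalog, mask: np.ndarray):
    """Per-(pair, codon) difference and site-count arrays for fast
    codon-bootstrap recomputation."""
    syn_sites, non_sites, sd_tab, nd_tab = _pair_tables()
    seqs = list(catalog.records.values())
    idx = np.array([_codon_indices(s) for s in seqs])  # (n_alleles, n_codons)
    n = len(seqs)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    kcod = np.flatnonzero(mask)
    P, K = len(pairs), len(kcod)
    sd = np.zeros((P, K))
    nd = np.zeros((P, K))
    ss = np.zeros((P, K))
    nn = np.zeros((P, K))
    for p, (i, j) in enumerate(pairs):
        a, b = idx[i, kcod], idx[j, kcod]
        ok = (a >= 0) & (b >= 0)
        aa, bb = a[ok], b[ok]
        sd[p, ok] = sd_tab[aa, bb]
        nd[p, ok] = nd_tab[aa, bb]
        ss[p, ok] = 0.5 * (syn_sites[aa] + syn_sites[bb])
        nn[p, ok] = 0.5 * (non_sites[aa] + non_sites[bb])
    return sd, nd, ss, nn


def _mean_distances(sd, nd, ss, nn, cols=None):
    """Pair-averaged JC-corrected dN and dS, given per-(pair,codon) arrays;
    ``cols`` is an optional bootstrap column index vector (with repeats)."""
    if cols is not None:
        sd, nd, ss, nn = sd[:, cols], nd[:, cols], ss[:, cols], nn[:, cols]
    S = ss.sum(axis=1)
    N = nn.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pS = np.where(S > 0, sd.sum(axis=1) / S, np.nan)
        pN = np.where(N > 0, nd.sum(axis=1) / N, np.nan)
        dS = np.where(pS < 0.75, -0.75 * np.log(1 - (4 / 3) * pS), np.nan)
        dN = np.where(pN < 0.75, -0.75 * np.log(1 - (4 / 3) * pN), np.nan)
    return float(np.nanmean(dN)), float(np.nanmean(dS))


def selection_z_test(
    catalog: AlleleCatalog,
    sites: SiteList | None = None,
    n_boot: int = 5000,
    seed: int = 0,
    alternative: str = "positive",
) -> SelectionResult:
    """Codon-bootstrap Z-test of dN = dS on a catalog (or site partition).

    dN and dS are pair-averaged over all allele pairs; the variance of
    (dN - dS) comes from resampling codon positions with replacement and
    recomputing both means each replicate.  ``alternative`` is "positive"
    (dN > dS, the classical positive-selection test), "negative" or
    "two-sided".
    """
    if len(catalog) < 2:
        raise ValueError("need at least 2 alleles")
    n_codons = catalog.aligned_length // 3
    mask = sites.mask() if sites is not None else np.ones(n_codons, dtype=bool)
    if mask.sum() < 5:
        raise ValueError("fewer than 5 codons in mask: variance unstable")
    sd, nd, ss, nn = _per_pair_per_codon(catalog, mask)
    dN, dS = _mean_distances(sd, nd, ss, nn)
    K = sd.shape[1]
    rng = np.random.default_rng(seed)
    # codon bootstrap: replicate b resamples K codons with replacement; the
    # per-pair sums are linear in the resample counts, so all replicates
    # reduce to one matrix product with a (K, n_boot) count matrix.
    counts = rng.multinomial(K, np.full(K, 1.0 / K), size=n_boot).T.astype(float)
    S = ss @ counts  # (P, n_boot)
    N = nn @ counts
    with np.errstate(divide="ignore", invalid="ignore"):
        pS = np.where(S > 0, (sd @ counts) / S, np.nan)
        pN = np.where(N > 0, (nd @ counts) / N, np.nan)
        bS = np.where(pS < 0.75, -0.75 * np.log(1 - (4 / 3) * pS), np.nan)
        bN = np.where(pN < 0.75, -0.75 * np.log(1 - (4 / 3) * pN), np.nan)
    diffs = np.nanmean(bN, axis=0) - np.nanmean(bS, axis=0)
    se = float(np.nanstd(diffs, ddof=1))
    z = (dN - dS) / se if se > 0 else float("inf") * np.sign(dN - dS)
    from scipy.stats import norm

    if alternative == "positive":
        p = float(norm.sf(z))
    elif alternative == "negative":
        p = float(norm.cdf(z))
    else:
        p = float(2 * norm.sf(abs(z)))
    label = sites.label if sites is not None else "all"
    return SelectionResult(
        partition=label,
        dN=dN,
        dS=dS,
        omega=dN / dS if dS > 0 else float("nan"),
        z=float(z),
        p_value=p,
        n_boot=n_boot,
        seed=seed,
        n_codons=int(mask.sum()),
        n_alleles=len(catalog),
    )
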