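"""Long-range haplotype reconstruction from unphased genotypes.

Maximum-likelihood EM over haplotype frequencies within small SNP windows,
combined with partition ligation across windows.  Missing genotypes are
summed over during the E-step and imputed to the posterior-modal allele in
the final reconstruction.

The per-window search space is exact: every haplotype pair compatible with
an individual's genotype (including all completions of missing sites) is
enumerated, so the EM solution is the maximum-likelihood frequency estimate
over the full compatible space for windows up to ``MAX_WINDOW`` SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "MAX_WINDOW",
    "PhasingError",
    "HaplotypeFrequencyTable",
    "PhasedCohort",
    "em_phase_window",
    "partition_ligation_phase",
    "switch_error_rate",
    "imputation_accuracy",
]

MAX_WINDOW = 12
MISSING = -1

#: hard cap on per-individual pair enumerations (guards missing blow-up)
_MAX_PAIRS = 1 << 16


class PhasingError(RuntimeError):
    pass


@dataclass
class HaplotypeFrequencyTable:
    """Estimated haplotype frequencies over one SNP window."""

    frequencies: dict[tuple[int, ...], float]

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise PhasingError(f"frequencies sum to {total}, expected 1")

    def top(self, k: int) -> list[tuple[int, ...]]:
        return [
            p
            for p, _ in sorted(
                self.frequencies.items(), key=lambda kv: (-kv[1], kv[0])
            )[:k]
        ]


@dataclass
class PhasedCohort:
    """Best-guess haplotype pair per individual with phase certainty."""

    haplotypes: np.ndarray  # (2n, m) int8
    phase_certainty: np.ndarray  # (n,) posterior prob of reported pair
    imputed_flags: np.ndarray  # (n, m) bool: genotype filled during phasing
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    def pair(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        return self.haplotypes[2 * i], self.haplotypes[2 * i + 1]


def _canonical(h1: tuple, h2: tuple) -> tuple[tuple, tuple]:
    return (h1, h2) if h1 <= h2 else (h2, h1)


def _compatible_pairs(g: np.ndarray) -> list[tuple[tuple, tuple]]:
    """All unordered haplotype pairs compatible with one genotype vector."""
    bad = ~np.isin(g, (0, 1, 2, MISSING))
    if bad.any():
        raise PhasingError(f"invalid genotype codes at sites {np.flatnonzero(bad)}")
    het = np.flatnonzero(g == 1)
    mis = np.flatnonzero(g == MISSING)
    if (1 << len(het)) * (1 << (2 * len(mis))) > _MAX_PAIRS:
        raise PhasingError("too many heterozygous/missing sites in window")
    base = (g == 2).astype(np.int8)
    pairs: set[tuple[tuple, tuple]] = set()
    for het_bits in product((0, 1), repeat=len(het)):
        for mis_bits in product(((0, 0), (0, 1), (1, 0), (1, 1)), repeat=len(mis)):
            h1 = base.copy()
            h2 = base.copy()
            h1[het] = het_bits
            h2[het] = 1 - np.array(het_bits, dtype=np.int8)
            for k, (x, y) in zip(mis, mis_bits):
                h1[k], h2[k] = x, y
            pairs.add(_canonical(tuple(h1.tolist()), tuple(h2.tolist())))
    return sorted(pairs)


def _em_over_pairs(
    pair_lists: list[list[tuple[tuple, tuple]]],
    tol: float,
    max_iter: int,
    init: dict[tuple, float] | None = None,
):
    """Frequency EM given each individual's compatible-pair list.

    Returns (freq dict, per-individual posterior arrays, log-likelihoods).
    The observed-data log-likelihood is asserted non-decreasing.
    """
    hap_index: dict[tuple, int] = {}
    i1, i2, owner = [], [], []
    for ind, pairs in enumerate(pair_lists):
        for h1, h2 in pairs:
            i1.append(hap_index.setdefault(h1, len(hap_index)))
            i2.append(hap_index.setdefault(h2, len(hap_index)))
            owner.append(ind)
    if not hap_index:
        raise PhasingError("no compatible haplotypes in window")
    i1 = np.array(i1)
    i2 = np.array(i2)
    owner = np.array(owner)
    coef = np.where(i1 == i2, 1.0, 2.0)
    n_hap = len(hap_index)
    n_ind = len(pair_lists)
    counts = np.array([len(p) for p in pair_lists])
    offsets = np.r_[0, np.cumsum(counts)[:-1]]

    if init is None:
        f = np.full(n_hap, 1.0 / n_hap)
    else:
        f = np.array([init.get(h, 0.0) for h in hap_index])
        f = (f + 1e-6) / (f + 1e-6).sum()

    logliks: list[float] = []
    for _ in range(max_iter):
        lik = coef * f[i1] * f[i2]
        sums = np.add.reduceat(lik, offsets)
        sums = np.maximum(sums, 1e-300)
        logliks.append(float(np.log(sums).sum()))
        if len(logliks) > 1 and logliks[-1] < logliks[-2] - 1e-8 * abs(logliks[-2]):
            raise AssertionError("EM log-likelihood decreased")
        post = lik / sums[owner]
        new = np.zeros(n_hap)
        np.add.at(new, i1, post)
        np.add.at(new, i2, post)
        new /= 2.0 * n_ind
        delta = float(np.abs(new - f).max())
        f = new
        if delta < tol:
            break
    lik = coef * f[i1] * f[i2]
    sums = np.maximum(np.add.reduceat(lik, offsets), 1e-300)
    post = lik / sums[owner]
    posteriors = [post[offsets[k]: offsets[k] + counts[k]] for k in range(n_ind)]
    haps = list(hap_index)
    freq = {h: float(f[hap_index[h]]) for h in haps}
    return freq, posteriors, logliks


def em_phase_window(
    genotypes: np.ndarray,
    window: tuple[int, int] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    freq_floor: float | None = None,
):
    """EM haplotype-frequency estimation over one SNP window.

    Parameters
    ----------
    genotypes
        (n, m) matrix with codes 0/1/2 and -1 for missing.
    window
        Half-open column interval; defaults to all columns.
    freq_floor
        Patterns below this frequency are pruned from the returned table
        (default ``1/(4n)``).

    Returns
    -------
    (table, posteriors, logliks, errors)
        ``posteriors[i]`` is a list of ``((h1, h2), probability)`` sorted by
        decreasing probability; individuals whose genotypes could not be
        phased appear in ``errors`` with an empty posterior.
    """
    g = np.asarray(genotypes)
    if window is not None:
        g = g[:, window[0]: window[1]]
    if g.shape[1] > MAX_WINDOW:
        raise PhasingError(f"window of {g.shape[1]} SNPs exceeds limit {MAX_WINDOW}")
    if tol <= 0:
        raise PhasingError("tol must be positive")

    pair_lists: list[list[tuple[tuple, tuple]]] = []
    errors: list[tuple[int, str]] = []
    ok_rows: list[int] = []
    for ind in range(g.shape[0]):
        try:
            pairs = _compatible_pairs(g[ind])
        except PhasingError as exc:
            errors.append((ind, str(exc)))
            continue
        ok_rows.append(ind)
        pair_lists.append(pairs)

    freq, post, logliks = _em_over_pairs(pair_lists, tol, max_iter)

    n = len(pair_lists)
    floor = 1.0 / (4 * n) if freq_floor is None else freq_floor
    kept = {h: f for h, f in freq.items() if f > floor}
    if not kept:  # degenerate tiny cohorts: keep the modal pattern
        top = max(freq, key=freq.get)
        kept = {top: freq[top]}
    total = sum(kept.values())
    table = HaplotypeFrequencyTable({h: f / total for h, f in kept.items()})

    posteriors: list[list[tuple[tuple[tuple, tuple], float]]] = [
        [] for _ in range(g.shape[0])
    ]
    for k, ind in enumerate(ok_rows):
        ranked = sorted(
            zip(pair_lists[k], post[k]), key=lambda kv: (-kv[1], kv[0])
        )
        posteriors[ind] = [(pair, float(p)) for pair, p in ranked]
    return table, posteriors, logliks, errors


def _prune_pairs(pairs, max_keep=20, rel_floor=1e-4):
    """Keep the dominant posterior pairs for one individual, renormalized."""
    if not pairs:
        return pairs
    best = pairs[0][1]
    kept = [(pp, p) for pp, p in pairs[: max_keep] if p >= rel_floor * best]
    total = sum(p for _, p in kept)
    return [(pp, p / total) for pp, p in kept]


def partition_ligation_phase(
    genotypes: np.ndarray,
    window_size: int = 8,
    top_patterns: int = 30,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> PhasedCohort:
    """Phase a cohort by windowed EM plus left-to-right ligation.

    Windows of ``window_size`` SNPs are EM-phased independently; adjacent
    blocks are then ligated by re-running EM over concatenations of each
    individual's surviving window pairs, retaining the ``top_patterns`` most
    frequent block haplotypes (individual best pairs are always kept).
    """
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if n < 2:
        raise PhasingError("at least 2 individuals required")
    if window_size > MAX_WINDOW:
        raise PhasingError(f"window_size exceeds limit {MAX_WINDOW}")

    bounds = [(s, min(s + window_size, m)) for s in range(0, m, window_size)]
    errors: list[tuple[int, str]] = []
    failed: set[int] = set()

    # per-block state: per-individual pruned pair lists [(pair, prob)]
    block_pairs: list[list[list[tuple[tuple[tuple, tuple], float]]]] = []
    for lo, hi in bounds:
        _table, post, _ll, errs = em_phase_window(g, (lo, hi), tol, max_iter)
        for ind, msg in errs:
            errors.append((ind, f"window [{lo},{hi}): {msg}"))
            failed.add(ind)
        block_pairs.append([_prune_pairs(p) for p in post])

    ok = [i for i in range(n) if i not in failed]

    current = block_pairs[0]
    for nxt in block_pairs[1:]:
        joint: list[list[tuple[tuple, tuple]]] = []
        weights: list[dict[tuple[tuple, tuple], float]] = []
        for ind in ok:
            combos: dict[tuple[tuple, tuple], float] = {}
            for (a1, a2), pa in current[ind]:
                for (b1, b2), pb in nxt[ind]:
                    for c1, c2 in ((a1 + b1, a2 + b2), (a1 + b2, a2 + b1)):
                        key = _canonical(c1, c2)
                        combos[key] = combos.get(key, 0.0) + 0.5 * pa * pb
            if not combos:
                raise PhasingError(f"individual {ind}: ligation produced no pairs")
            joint.append(sorted(combos))
            weights.append(combos)
        init: dict[tuple, float] = {}
        for wmap in weights:
            for (h1, h2), p in wmap.items():
                init[h1] = init.get(h1, 0.0) + p
                init[h2] = init.get(h2, 0.0) + p
        total = sum(init.values())
        init = {h: p / total for h, p in init.items()}

        freq, post, _ll = _em_over_pairs(joint, tol, max_iter, init=init)

        retained = set(
            h
            for h, _ in sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))[
                :top_patterns
            ]
        )
        merged: list[list[tuple[tuple[tuple, tuple], float]]] = [
            [] for _ in range(n)
        ]
        for k, ind in enumerate(ok):
            ranked = sorted(
                zip(joint[k], post[k]), key=lambda kv: (-kv[1], kv[0])
            )
            # the modal pair always survives retention
            best = ranked[0][0]
            retained.add(best[0])
            retained.add(best[1])
            kept = [
                (pair, float(p))
                for pair, p in ranked
                if pair[0] in retained and pair[1] in retained and p > 0
            ]
            merged[ind] = _prune_pairs(kept or [(best, 1.0)])
        if not retained:
            raise PhasingError("ligation retained zero patterns")
        current = merged

    haplotypes = np.zeros((2 * n, m), dtype=np.int8)
    certainty = np.zeros(n)
    imputed = np.zeros((n, m), dtype=bool)
    for ind in range(n):
        if ind in failed or not current[ind]:
            # deterministic genotype-compatible fallback
            gi = g[ind]
            h1 = np.where(gi == 2, 1, 0).astype(np.int8)
            h2 = h1.copy()
            h1[gi == 1] = 1
            h1[gi == MISSING] = 0
            h2[gi == MISSING] = 0
            pair, cert = (tuple(h1.tolist()), tuple(h2.tolist())), np.nan
            if ind not in failed:
                errors.append((ind, "no surviving pair after ligation"))
        else:
            pair, cert = current[ind][0]
        h1, h2 = sorted(pair)
        haplotypes[2 * ind] = h1
        haplotypes[2 * ind + 1] = h2
        certainty[ind] = cert
        imputed[ind] = g[ind] == MISSING
    return PhasedCohort(haplotypes, certainty, imputed, errors)


# ---------------------------------------------------------------------------
# evaluation helpers against simulator truth


def switch_error_rate(
    phased: PhasedCohort, truth_haplotypes: np.ndarray
) -> float:
    """Fraction of adjacent truth-heterozygous site pairs phased discordantly."""
    n = phased.n_individuals
    switches = 0
    opportunities = 0
    for i in range(n):
        t1, t2 = truth_haplotypes[2 * i], truth_haplotypes[2 * i + 1]
        p1, p2 = phased.pair(i)
        het = np.flatnonzero((t1 != t2) & (p1 != p2))
        if het.size < 2:
            continue
        orient = (p1[het] == t1[het]).astype(int)
        switches += int(np.sum(orient[1:] != orient[:-1]))
        opportunities += het.size - 1
    return switches / opportunities if opportunities else 0.0


def imputation_accuracy(
    phased: PhasedCohort, observed: np.ndarray, truth_genotypes: np.ndarray
) -> float:
    """Accuracy of genotypes imputed during phasing at missing entries."""
    miss = np.asarray(observed) == MISSING
    if not miss.any():
        return 1.0
    n = phased.n_individuals
    filled = (phased.haplotypes[0::2] + phased.haplotypes[1::2]).reshape(
        n, -1
    )
    return float(np.mean(filled[miss] == np.asarray(truth_genotypes)[miss]))
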