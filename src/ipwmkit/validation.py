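r"""Validation statistics for derived motifs.

Four independent checks distinguish a genuine binding motif from the
low-complexity "noise" patterns that dominate weak ChIP-seq peaks:

1. the **null Ri distribution** — scan a composition-matched random sequence
   and fit a Gaussian to the window scores; the upper-tail probability at 0
   is the false-positive rate for calling a "potentially functional" site
   (Ri > 0);
2. **positional mutual information** — the total pairwise MI between site
   positions as a percentage of Rsequence measures how much of the motif's
   information an additive (position-independent) model misses;
3. **matrix distance** — normalized Euclidean distance in bits/nt against an
   independently derived reference motif (see
   :func:`ipwmkit.information.euclidean_distance`);
4. the **Ri-vs-binding-energy F-test** — for a real motif, stronger sites
   (higher Ri) sit in stronger peaks (lower binding energy), so regressing
   the energy proxy E = -log2(signal) on Ri gives a clearly negative slope
   and a large F statistic; noise motifs give slopes near 0 and small F.
   F distributions of motif vs noise populations are compared by
   Mann-Whitney U.

The cofactor intersite-distance analysis (enrichment of primary→cofactor
site separations below 20 nt) supports co-binding claims.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .information import (
    AlignedSites,
    Model,
    BindingSite,
    build_frequency_matrix,
    build_ipwm,
)
from .io_formats import PeakDataset
from .seq import ALPHABET, encode

F_CAP = 1e12


# ---------------------------------------------------------------------------
# composition-matched null sequences


def _transition_counts(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    mono = np.zeros(4)
    trans = np.zeros((4, 4))
    for s in seqs:
        codes = encode(s)
        codes = codes[codes < 4]
        if len(codes) == 0:
            continue
        mono += np.bincount(codes, minlength=4)
        if len(codes) > 1:
            trans += np.histogram2d(
                codes[:-1], codes[1:], bins=[np.arange(5)] * 2
            )[0]
    return mono, trans


def composition_preserving_sequence(
    source, length: int = 10_000, seed: int = 0
) -> str:
    """Random sequence conserving the source's mono- and dinucleotide
    composition (a first-order Markov chain fitted to the source).

    ``source`` may be a :class:`PeakDataset`, a sequence string, or a list
    of strings.  Degenerate single-letter sources emit that letter run.
    """
    if isinstance(source, PeakDataset):
        seqs = source.sequences()
    elif isinstance(source, str):
        seqs = [source]
    else:
        seqs = list(source)
    mono, trans = _transition_counts(seqs)
    if mono.sum() < 1:
        raise ValueError("source contains no unambiguous bases")
    present = mono > 0
    if present.sum() == 1:
        b = int(np.argmax(mono))
        return ALPHABET[b] * length
    if trans.sum() < 100:
        raise ValueError("source too small: need >= 100 dinucleotide observations")
    rng = np.random.default_rng(seed)
    p0 = mono / mono.sum()
    rows = trans.sum(axis=1, keepdims=True)
    # rows never observed fall back to the mononucleotide distribution
    P = np.where(rows > 0, trans / np.where(rows > 0, rows, 1.0), p0)
    out = np.empty(length, dtype=np.int8)
    out[0] = rng.choice(4, p=p0)
    # draw all uniforms at once, then walk the chain
    u = rng.random(length)
    cum = np.cumsum(P, axis=1)
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i])
    return "".join(ALPHABET[c] for c in out)


def fitted_transition_matrix(source) -> np.ndarray:
    """The 4x4 dinucleotide transition matrix (rows sum to 1)."""
    if isinstance(source, PeakDataset):
        seqs = source.sequences()
    elif isinstance(source, str):
        seqs = [source]
    else:
        seqs = list(source)
    mono, trans = _transition_counts(seqs)
    rows = trans.sum(axis=1, keepdims=True)
    p0 = mono / mono.sum()
    return np.where(rows > 0, trans / np.where(rows > 0, rows, 1.0), p0)


# ---------------------------------------------------------------------------
# null Ri distribution


@dataclass
class NullDistribution:
    mean: float
    sd: float
    p_positive: float
    n: int
    degenerate: bool = False


def null_distribution(model: Model, nullseq: str) -> NullDistribution:
    """Gaussian fit to the Ri of every window (both strands, all spacers) of
    a composition-matched random sequence; ``p_positive`` is the upper-tail
    probability of Ri > 0, the expected false-positive site rate."""
    from .scanning import window_scores
    from .seq import encode

    *_, scores = window_scores(model, encode(nullseq), "both")
    if scores.size == 0:
        raise ValueError("null sequence shorter than the model span")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
    if sd <= 0:
        return NullDistribution(mean, sd, float(mean > 0), scores.size, degenerate=True)
    return NullDistribution(
        mean, sd, float(stats.norm.sf(0.0, loc=mean, scale=sd)), scores.size
    )


# ---------------------------------------------------------------------------
# positional mutual information


def _pairwise_mi(mat: np.ndarray) -> np.ndarray:
    """MI(i,j) in bits for all column pairs of an (n, L) code matrix."""
    n, L = mat.shape
    marg = np.zeros((L, 4))
    for b in range(4):
        marg[:, b] = (mat == b).sum(axis=0)
    marg /= n
    mi = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            joint = np.bincount(4 * mat[:, i] + mat[:, j], minlength=16) / n
            joint = joint.reshape(4, 4)
            indep = np.outer(marg[i], marg[j])
            mask = joint > 0
            mi[i, j] = float(
                np.sum(joint[mask] * np.log2(joint[mask] / indep[mask]))
            )
    return mi


@dataclass
class MutualInformationResult:
    total: float
    percent_of_rsequence: float
    pair_mi: np.ndarray       # bias-corrected, clipped at 0, upper triangle
    raw_pair_mi: np.ndarray
    rsequence: float


def mutual_information_total(
    sites: AlignedSites, n_permutations: int = 100, seed: int = 0
) -> MutualInformationResult:
    """Total interpositional MI and its percentage of Rsequence.

    Finite samples inflate MI even for independent columns, so each pair's
    MI is bias-corrected by subtracting the mean MI of column-wise permuted
    alignments (columns shuffled independently across sites, destroying
    correlations while keeping marginals), then clipped at 0.
    """
    if sites.n_included < 30:
        raise ValueError("mutual information needs >= 30 sites")
    mat = sites.site_codes().astype(np.int64)
    n, L = mat.shape
    raw = _pairwise_mi(mat)
    rng = np.random.default_rng(seed)
    bias = np.zeros_like(raw)
    perm = mat.copy()
    for _ in range(n_permutations):
        for j in range(L):
            rng.shuffle(perm[:, j])
        bias += _pairwise_mi(perm)
    bias /= n_permutations
    corrected = np.clip(raw - bias, 0.0, None)
    total = float(corrected.sum())
    model = build_ipwm(build_frequency_matrix(sites))
    if model.rsequence <= 0:
        raise ValueError("Rsequence <= 0: MI percentage undefined")
    return MutualInformationResult(
        total=total,
        percent_of_rsequence=100.0 * total / model.rsequence,
        pair_mi=corrected,
        raw_pair_mi=raw,
        rsequence=model.rsequence,
    )


# ---------------------------------------------------------------------------
# Ri vs binding energy


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    F: float
    p_value: float
    n: int
    r_squared: float


def default_energy_transform(signals: np.ndarray) -> np.ndarray:
    """Binding-energy proxy: E = -log2(peak signal).

    Occupancy grows with signal and falls with binding energy, so a
    monotone decreasing log transform of the signal stands in for energy.
    """
    signals = np.asarray(signals, dtype=float)
    if np.any(signals <= 0):
        raise ValueError("signals must be positive for the energy transform")
    return -np.log2(signals)


def ri_energy_ftest(
    ri: np.ndarray, signals: np.ndarray, energy_transform=default_energy_transform
) -> RegressionResult:
    """OLS of binding energy on Ri with the regression F statistic (1, n-2 df).

    True motifs show slope well below 0 with very large F; noise motifs show
    slope near 0.  A perfectly collinear fit reports F capped at 1e12.
    """
    ri = np.asarray(ri, dtype=float)
    if len(ri) < 3:
        raise ValueError("need at least 3 (Ri, signal) pairs")
    if np.std(ri) == 0:
        raise ValueError("zero-variance Ri: regression undefined")
    energy = energy_transform(np.asarray(signals, dtype=float))
    n = len(ri)
    fit = stats.linregress(ri, energy)
    r2 = fit.rvalue**2
    if 1.0 - r2 < 1e-15:
        F = F_CAP
        p = 0.0
    else:
        F = min(F_CAP, r2 * (n - 2) / (1.0 - r2))
        p = float(stats.f.sf(F, 1, n - 2))
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        F=float(F), p_value=p, n=n, r_squared=float(r2),
    )


def compare_f_distributions(
    f_true: list[float], f_noise: list[float]
) -> tuple[float, float]:
    """Mann-Whitney U (two-sided) between motif and noise F-value samples.

    Returns (U of the first sample, P).  Exact for small tie-free samples,
    normal approximation with tie correction otherwise (scipy's default).
    """
    if len(f_true) == 0 or len(f_noise) == 0:
        raise ValueError("both F samples must be non-empty")
    res = stats.mannwhitneyu(f_true, f_noise, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cofactor intersite distances


@dataclass
class IntersiteResult:
    distances: np.ndarray     # one minimum distance per peak with both kinds
    fraction_below: float     # fraction of peaks with distance < cutoff
    cutoff: int
    n_peaks: int

    def histogram(self, bins=None) -> tuple[np.ndarray, np.ndarray]:
        if bins is None:
            upper = int(self.distances.max()) + 2 if self.distances.size else 2
            bins = np.arange(0, upper)
        return np.histogram(self.distances, bins=bins)


def intersite_distance_distribution(
    primary_sites: list[BindingSite],
    cofactor_sites: list[BindingSite],
    primary_rsequence: float,
    cofactor_rsequence: float,
    threshold_mode: str = "rsequence",
    cutoff: int = 20,
) -> IntersiteResult:
    """Minimum edge-to-edge separation between primary and cofactor sites
    per peak, after a minimum-information filter on Ri.

    ``threshold_mode`` "rsequence" keeps sites with Ri >= Rsequence of their
    own motif; "half-rsequence" relaxes to 0.5*Rsequence (used when the
    stricter filter eliminates too many cofactor sites).  Overlapping sites
    count as distance 0, which lands in the < ``cutoff`` bin.
    """
    if threshold_mode not in ("rsequence", "half-rsequence"):
        raise ValueError("threshold_mode must be 'rsequence' or 'half-rsequence'")
    scale = 1.0 if threshold_mode == "rsequence" else 0.5
    p_thr = scale * primary_rsequence
    c_thr = scale * cofactor_rsequence

    def by_peak(sites, thr):
        d: dict[str, list[BindingSite]] = {}
        for s in sites:
            if s.ri >= thr:
                d.setdefault(s.seq_id, []).append(s)
        return d

    prim = by_peak(primary_sites, p_thr)
    cof = by_peak(cofactor_sites, c_thr)
    dists = []
    for peak_id in sorted(set(prim) & set(cof)):
        best = np.inf
        for a in prim[peak_id]:
            for b in cof[peak_id]:
                gap = max(a.start, b.start) - min(a.end, b.end)
                best = min(best, max(0, gap))
        dists.append(best)
    dists = np.array(dists, dtype=float)
    frac = float(np.mean(dists < cutoff)) if dists.size else 0.0
    return IntersiteResult(dists, frac, cutoff, len(dists))
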