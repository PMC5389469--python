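r"""Shannon-information core: frequency matrices, information weight matrices
(iPWMs), individual-information (Ri) scoring and matrix comparison.

An iPWM assigns each base :math:`b` at each site position :math:`l` a weight

.. math:: w(b,l) = 2 + \log_2 f'(b,l) - e(n)

in bits, where :math:`f'` is the (lightly pseudocounted) base frequency among
the :math:`n` aligned training sites, 2 bits is the information of a uniform
four-letter background, and :math:`e(n)` is the small-sample correction — the
expected overestimate of information when frequencies are estimated from only
:math:`n` sites.  The individual information of a site is the sum of the
weights of its bases,

.. math:: R_i = \sum_l w(s_l, l),

and is a proxy for binding affinity: a difference of :math:`\Delta R_i` bits
corresponds to a :math:`2^{\Delta R_i}`-fold affinity change.  The average
information of the motif, :math:`R_{sequence}`, is the mean :math:`R_i` of the
training sites.

Weights use a *uniform* background, not the genomic composition: the
protein–DNA contacts a weight matrix models do not depend on the composition
of the surrounding genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import stats

from .patterns import SearchPattern
from .seq import encode, revcomp_codes

PSEUDOCOUNT = 0.25  # per-base; keeps log2 finite at zero counts
GAP_PSEUDOCOUNT = 0.25


# ---------------------------------------------------------------------------
# small-sample correction

_ASYMPTOTIC_N = 100_000  # above this, 3/(2 n ln 2) agrees to < 1e-9 bits


@lru_cache(maxsize=4096)
def small_sample_correction(n: int) -> float:
    r"""Expected information overestimate :math:`e(n) = 2 - E[H_n]` in bits.

    :math:`E[H_n]` is the expected plug-in entropy of ``n`` draws from the
    uniform 4-letter distribution.  Computed exactly through the binomial
    marginal of each letter's count,

    .. math:: E[H_n] = 4\,E\!\left[-\tfrac{X}{n}\log_2\tfrac{X}{n}\right],
              \quad X \sim \mathrm{Binomial}(n, 1/4),

    for all practical ``n``; the first-order asymptotic
    :math:`3/(2 n \ln 2)` is used only for very large ``n`` where it is
    indistinguishable.  Monotone non-increasing; e(1) = 2, e(n) -> 0.
    """
    if n < 1:
        raise ValueError("site count must be >= 1")
    if n > _ASYMPTOTIC_N:
        return 3.0 / (2.0 * n * math.log(2.0))
    x = np.arange(1, n + 1)
    pmf = stats.binom.pmf(x, n, 0.25)
    frac = x / n
    g = -frac * np.log2(frac)
    return float(2.0 - 4.0 * np.sum(pmf * g))


# ---------------------------------------------------------------------------
# aligned sites and matrices


@dataclass
class AlignedSites:
    """A multiple local alignment: one candidate site per input sequence.

    ``offsets``/``strands``/``gaps`` give each sequence's site placement;
    sequences with ``included[i] == False`` contribute no site (their other
    assignment fields are ignored).  ``gaps`` is only meaningful for
    bipartite patterns.
    """

    sequences: list[str]
    pattern: SearchPattern
    offsets: np.ndarray
    strands: np.ndarray  # '+' / '-'
    gaps: np.ndarray | None = None
    included: np.ndarray | None = None
    _codes: list[np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.strands = np.asarray(self.strands)
        if self.gaps is not None:
            self.gaps = np.asarray(self.gaps, dtype=int)
        elif self.pattern.kind == "bipartite":
            raise ValueError("bipartite alignment requires gaps")
        if self.included is None:
            self.included = np.ones(len(self.sequences), dtype=bool)
        else:
            self.included = np.asarray(self.included, dtype=bool)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def codes(self) -> list[np.ndarray]:
        if self._codes is None:
            self._codes = [encode(s) for s in self.sequences]
        return self._codes

    def site_codes(self) -> np.ndarray:
        """(n_included, width) base codes in motif orientation.

        Reverse-strand sites contribute the reverse complement of their
        genomic window; bipartite sites contribute the two half sites with
        the spacer removed.
        """
        pat = self.pattern
        rows = []
        codes = self.codes()
        for i in np.flatnonzero(self.included):
            gap = int(self.gaps[i]) if self.gaps is not None else 0
            span = pat.span(gap) if pat.kind == "bipartite" else pat.left
            o = int(self.offsets[i])
            window = codes[i][o : o + span]
            if self.strands[i] == "-":
                window = revcomp_codes(window)
            if pat.kind == "bipartite":
                window = np.concatenate([window[: pat.left], window[pat.left + gap :]])
            rows.append(window)
        return np.asarray(rows, dtype=np.int8)

    def gap_histogram(self) -> np.ndarray:
        if self.pattern.kind != "bipartite":
            raise ValueError("gap histogram only defined for bipartite alignments")
        g = self.gaps[self.included] - self.pattern.gap_min
        return np.bincount(g, minlength=self.pattern.n_gaps)


@dataclass
class FrequencyMatrix:
    """Per-position base frequencies of an aligned site set (4 x L)."""

    freqs: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape[0] != 4:
            raise ValueError("frequency matrix must be 4 x L")
        if np.any(self.freqs < 0):
            raise ValueError("negative frequency")
        colsums = self.freqs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("columns must sum to 1")

    @property
    def length(self) -> int:
        return self.freqs.shape[1]


def position_entropies(freqs: np.ndarray) -> np.ndarray:
    """Shannon entropy of each column in bits (0*log 0 := 0)."""
    f = np.asarray(freqs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, -f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    return terms.sum(axis=0)


@dataclass
class InformationWeightMatrix:
    """An iPWM: per-position base weights in bits, with provenance.

    ``rsequence`` is the mean training-site Ri, computed as
    ``sum(freqs * weights)`` so the definitional identity "Rsequence = mean
    Ri of the training sites" holds exactly.  ``entropies`` are the raw
    per-column Shannon entropies H(l).
    """

    weights: np.ndarray
    freqs: np.ndarray
    n: int
    e_n: float
    rsequence: float
    entropies: np.ndarray

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def width(self) -> int:
        return self.length

    @property
    def rsequence_per_nt(self) -> float:
        return self.rsequence / self.length

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[b] for b in np.argmax(self.weights, axis=0))

    def reverse_complement(self) -> "InformationWeightMatrix":
        return replace(
            self,
            weights=self.weights[::-1, ::-1].copy(),
            freqs=self.freqs[::-1, ::-1].copy(),
            entropies=self.entropies[::-1].copy(),
        )

    def score_codes(self, window: np.ndarray) -> float:
        if np.any(window >= 4):
            raise ValueError("ambiguous base (N) in scoring window")
        return float(self.weights[window, np.arange(self.length)].sum())


@dataclass
class BipartiteModel:
    """Two half-site iPWMs separated by a variable spacer (``l<a,b>r``).

    ``gap_hist[k]`` counts training sites with spacer ``gap_min + k``.  Ri of
    a site is by default the sum of the two half-site Ri values; with
    ``include_gap_information`` an extra ``log2((b-a+1) * f_gap(g))`` term
    rewards sites with the preferred spacer.
    """

    left: InformationWeightMatrix
    right: InformationWeightMatrix
    pattern: SearchPattern
    gap_hist: np.ndarray
    include_gap_information: bool = False

    def __post_init__(self) -> None:
        self.gap_hist = np.asarray(self.gap_hist, dtype=float)
        if self.gap_hist.shape[0] != self.pattern.n_gaps:
            raise ValueError("gap histogram length must match the gap range")

    @property
    def n(self) -> int:
        return self.left.n

    @property
    def width(self) -> int:
        return self.pattern.width

    @property
    def dominant_gap(self) -> int:
        # ties broken toward the smaller spacer
        return int(self.pattern.gap_min + np.argmax(self.gap_hist))

    @property
    def rsequence(self) -> float:
        return self.left.rsequence + self.right.rsequence

    @property
    def rsequence_per_nt(self) -> float:
        return self.rsequence / self.width

    @property
    def weights(self) -> np.ndarray:
        """Concatenated half-site weights (4 x (l+r)), spacer excluded."""
        return np.concatenate([self.left.weights, self.right.weights], axis=1)

    def gap_information(self, gap: int) -> float:
        k = self.pattern.n_gaps
        idx = gap - self.pattern.gap_min
        if not 0 <= idx < k:
            raise ValueError(f"gap {gap} outside pattern range")
        total = self.gap_hist.sum()
        f_gap = (self.gap_hist[idx] + GAP_PSEUDOCOUNT) / (total + k * GAP_PSEUDOCOUNT)
        return float(np.log2(k * f_gap))


Model = InformationWeightMatrix | BipartiteModel


@dataclass
class BindingSite:
    """A located, stranded binding site with its individual information.

    ``start``/``end`` are 0-based half-open coordinates on the named
    sequence; for bipartite sites ``end - start = l + gap + r``.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    ri: float
    sequence: str = ""
    gap: int | None = None
    rank: int | None = None


# ---------------------------------------------------------------------------
# construction


def build_frequency_matrix(sites: AlignedSites) -> FrequencyMatrix:
    """Base frequencies of the aligned sites (reverse-strand sites enter as
    their reverse complement)."""
    if sites.n_included < 1:
        raise ValueError("no included sites")
    mat = sites.site_codes()
    if np.any(mat >= 4):
        raise ValueError("ambiguous base inside an aligned site")
    counts = _count_columns(mat)
    return FrequencyMatrix(counts / mat.shape[0], n=mat.shape[0])


def _count_columns(mat: np.ndarray) -> np.ndarray:
    L = mat.shape[1]
    counts = np.zeros((4, L))
    for b in range(4):
        counts[b] = (mat == b).sum(axis=0)
    return counts


def build_ipwm(fm: FrequencyMatrix) -> InformationWeightMatrix:
    """Turn a frequency matrix into an iPWM under a uniform background.

    The pseudocounted frequency ``f' = (count + 0.25)/(n + 1)`` is used only
    inside the log so zero-count weights stay finite; entropies use the raw
    frequencies.
    """
    n = fm.n
    e_n = small_sample_correction(n)
    counts = fm.freqs * n
    f_prime = (counts + PSEUDOCOUNT) / (n + 4 * PSEUDOCOUNT)
    weights = 2.0 + np.log2(f_prime) - e_n
    rsequence = float(np.sum(fm.freqs * weights))
    return InformationWeightMatrix(
        weights=weights,
        freqs=fm.freqs.copy(),
        n=n,
        e_n=e_n,
        rsequence=rsequence,
        entropies=position_entropies(fm.freqs),
    )


def ipwm_from_sites(sites: AlignedSites) -> Model:
    """Build the model (contiguous or bipartite) from an alignment."""
    if sites.pattern.kind == "contiguous":
        return build_ipwm(build_frequency_matrix(sites))
    mat = sites.site_codes()
    if np.any(mat >= 4):
        raise ValueError("ambiguous base inside an aligned site")
    l = sites.pattern.left
    n = mat.shape[0]
    left = build_ipwm(FrequencyMatrix(_count_columns(mat[:, :l]) / n, n=n))
    right = build_ipwm(FrequencyMatrix(_count_columns(mat[:, l:]) / n, n=n))
    return BipartiteModel(
        left=left,
        right=right,
        pattern=sites.pattern,
        gap_hist=sites.gap_histogram(),
    )


# ---------------------------------------------------------------------------
# scoring


def score_site(
    m: InformationWeightMatrix, seq: str | np.ndarray, offset: int, strand: str = "+"
) -> float:
    """Ri (bits) of the window starting at ``offset`` on the given strand.

    Reverse-strand scoring evaluates the reverse complement of the window.
    Windows containing N raise ``ValueError``.
    """
    codes = encode(seq) if isinstance(seq, str) else seq
    if offset < 0 or offset + m.length > len(codes):
        raise ValueError("window does not fit in sequence")
    window = codes[offset : offset + m.length]
    if strand == "-":
        window = revcomp_codes(window)
    return m.score_codes(window)


def score_bipartite(
    bm: BipartiteModel,
    seq: str | np.ndarray,
    offset: int,
    gap: int,
    strand: str = "+",
) -> float:
    """Ri of a bipartite site: left-half Ri + right-half Ri (+ optional
    spacer-length information)."""
    pat = bm.pattern
    if not (pat.gap_min <= gap <= pat.gap_max):
        raise ValueError(f"gap {gap} outside [{pat.gap_min},{pat.gap_max}]")
    codes = encode(seq) if isinstance(seq, str) else seq
    span = pat.span(gap)
    if offset < 0 or offset + span > len(codes):
        raise ValueError("window does not fit in sequence")
    window = codes[offset : offset + span]
    if strand == "-":
        window = revcomp_codes(window)
    ri = bm.left.score_codes(window[: pat.left]) + bm.right.score_codes(
        window[pat.left + gap :]
    )
    if bm.include_gap_information:
        ri += bm.gap_information(gap)
    return float(ri)


def affinity_fold(ri_1: float, ri_2: float) -> float:
    """Fold change in binding affinity between two sites: 2^(Ri1 - Ri2)."""
    return float(2.0 ** (ri_1 - ri_2))


@dataclass
class DeltaRi:
    delta: float
    outside: bool = False


def delta_ri(
    m: Model, site_sequence: str, position: int, ref: str, alt: str
) -> DeltaRi:
    """Predicted change in site strength for a substitution variant.

    ``position`` is 0-based within the site.  Positive delta predicts
    strengthened binding, negative weakened.  Variants outside the site
    window return 0 with ``outside=True``.  For bipartite models the site
    sequence is the concatenated half sites (spacer variants carry no weight
    and count as outside).
    """
    weights = m.weights if isinstance(m, BipartiteModel) else m.weights
    L = weights.shape[1]
    if position < 0 or position >= L:
        return DeltaRi(0.0, outside=True)
    if site_sequence[position].upper() != ref.upper():
        raise ValueError(
            f"reference base {ref!r} does not match site sequence "
            f"{site_sequence[position]!r} at position {position}"
        )
    if ref.upper() == alt.upper():
        return DeltaRi(0.0)
    bi = "ACGT".index(ref.upper())
    bj = "ACGT".index(alt.upper())
    return DeltaRi(float(weights[bj, position] - weights[bi, position]))


# ---------------------------------------------------------------------------
# matrix comparison


def _weights_of(m: Model) -> np.ndarray:
    return m.weights


def _revcomp_weights(w: np.ndarray) -> np.ndarray:
    return w[::-1, ::-1]


def _direct_distance(w1: np.ndarray, w2: np.ndarray) -> float:
    L = w1.shape[1]
    return float(np.sqrt(np.sum((w1 - w2) ** 2)) / L)


def euclidean_distance(
    m1: Model, m2: Model, *, strand_sensitive: bool = False, min_overlap: int | None = None
) -> float:
    """Normalized Euclidean distance between two weight matrices (bits/nt).

    Equal lengths: ``sqrt(sum (w1-w2)^2) / L``, minimized over the reverse
    complement of one matrix unless ``strand_sensitive`` (motif alignments
    are strand-ambiguous; the symmetrized form is still a metric).  Unequal
    lengths: minimum over all full-overlap offsets of the shorter matrix
    against the longer (and its reverse complement), normalized by the
    overlap length.  ``min_overlap`` relaxes full overlap to allow slightly
    shifted comparisons.
    """
    w1, w2 = _weights_of(m1), _weights_of(m2)
    if w1.shape[1] == w2.shape[1] and min_overlap is None:
        d = _direct_distance(w1, w2)
        if not strand_sensitive:
            d = min(d, _direct_distance(w1, _revcomp_weights(w2)))
        return d
    if w1.shape[1] > w2.shape[1]:
        w1, w2 = w2, w1  # w1 is the shorter
    s, L = w1.shape[1], w2.shape[1]
    lo = s if min_overlap is None else min(min_overlap, s)
    if lo < 1:
        raise ValueError("zero overlap between matrices")
    best = np.inf
    variants = [w2] if strand_sensitive else [w2, _revcomp_weights(w2)]
    for wl in variants:
        for off in range(-(s - lo), L - lo + 1):
            a0, a1 = max(0, -off), min(s, L - off)
            if a1 - a0 < lo:
                continue
            seg1 = w1[:, a0:a1]
            seg2 = wl[:, a0 + off : a1 + off]
            ov = a1 - a0
            best = min(best, float(np.sqrt(np.sum((seg1 - seg2) ** 2)) / ov))
    if not np.isfinite(best):
        raise ValueError("zero overlap between matrices")
    return best
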