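"""Synthetic ranked peak datasets with known ground truth.

The generator emulates the structure of a ranked ChIP-seq peak set as the
discovery pipeline assumes it: a primary motif embedded preferentially in
strong peaks, optional cofactor sites a short distance from the primary
site, low-complexity content dominating the weak peaks, and peak signals
that grow with site strength (signal = s0 * 2^(beta * Ri) * lognormal
noise), so that Ri and signal are positively associated whenever beta > 0.
Every stage of discovery and validation can be tested against the recorded
ground truth without any downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .information import (
    FrequencyMatrix,
    InformationWeightMatrix,
    build_ipwm,
    score_site,
)
from .io_formats import Peak, PeakDataset
from .seq import ALPHABET, revcomp


# ---------------------------------------------------------------------------
# generating matrices


def consensus_frequency_matrix(consensus: str, conservation: float = 0.85) -> FrequencyMatrix:
    """Frequency matrix with the consensus base at probability
    ``conservation`` and the rest spread evenly."""
    if not 0.25 <= conservation <= 1.0:
        raise ValueError("conservation must be in [0.25, 1]")
    L = len(consensus)
    f = np.full((4, L), (1.0 - conservation) / 3.0)
    for l, c in enumerate(consensus.upper()):
        f[ALPHABET.index(c), l] = conservation
    return FrequencyMatrix(f, n=1)


def matrix_with_information(
    consensus: str, total_bits: float
) -> FrequencyMatrix:
    """Frequency matrix over the given consensus whose asymptotic information
    content (2 - H per column, summed) equals ``total_bits``.

    Solves for the per-column conservation level numerically; columns share
    one conservation value, so information is spread evenly.
    """
    L = len(consensus)
    per_col = total_bits / L
    if not 0 <= per_col < 2:
        raise ValueError("per-column information must be in [0, 2) bits")

    def info(p):
        q = (1.0 - p) / 3.0
        h = -p * np.log2(p) - 3 * q * np.log2(q) if 0 < p < 1 else 0.0
        return 2.0 - h

    p = optimize.brentq(lambda p: info(p) - per_col, 0.25 + 1e-12, 1 - 1e-9)
    return consensus_frequency_matrix(consensus, p)


# ---------------------------------------------------------------------------
# site sampling


def sample_sites(fm: FrequencyMatrix, n: int, seed_or_rng=0) -> list[str]:
    """n i.i.d. site sequences drawn column-wise from the frequency matrix."""
    rng = _as_rng(seed_or_rng)
    L = fm.length
    cum = np.cumsum(fm.freqs, axis=0)
    u = rng.random((n, L))
    codes = (u[:, None, :] > cum[None, :, :]).sum(axis=1)
    return ["".join(ALPHABET[c] for c in row) for row in codes]


def generate_bipartite_sites(
    left_fm: FrequencyMatrix,
    right_fm: FrequencyMatrix,
    gap_distribution: np.ndarray,
    gap_min: int,
    n: int,
    seed_or_rng=0,
    background: np.ndarray | None = None,
) -> tuple[list[str], np.ndarray]:
    """n full bipartite site sequences (left + spacer + right) with recorded
    spacer lengths; spacer bases are drawn from the background composition."""
    rng = _as_rng(seed_or_rng)
    gap_distribution = np.asarray(gap_distribution, dtype=float)
    if not np.isclose(gap_distribution.sum(), 1.0):
        raise ValueError("gap distribution must sum to 1")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    lefts = sample_sites(left_fm, n, rng)
    rights = sample_sites(right_fm, n, rng)
    gaps = gap_min + rng.choice(len(gap_distribution), size=n, p=gap_distribution)
    sites = []
    for i in range(n):
        spacer = "".join(ALPHABET[c] for c in rng.choice(4, size=gaps[i], p=bg))
        sites.append(lefts[i] + spacer + rights[i])
    return sites, gaps


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# dataset specification


@dataclass
class SimSpec:
    """Conditions for one synthetic ranked peak dataset.

    Defaults reflect a realistic mid-size ChIP-seq experiment at desk scale:
    500 peaks of 200 nt, a 12-bit primary motif carried by 90% of peaks, and
    a clear signal-affinity coupling (beta = 1, lognormal noise sigma = 0.5
    on the natural-log scale).
    """

    n_peaks: int = 500
    peak_length: int = 200
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    primary: FrequencyMatrix | None = None
    # bipartite alternative to `primary`
    left: FrequencyMatrix | None = None
    right: FrequencyMatrix | None = None
    gap_distribution: np.ndarray | None = None
    gap_min: int = 0
    carrier_fraction: float = 0.9
    n_carriers: int | None = None   # exact carrier count (overrides fraction)
    carriers_on_top: bool = False   # force carriers to occupy the top ranks
    cofactor: FrequencyMatrix | None = None
    cofactor_fraction: float = 0.0
    cofactor_distance: int = 10     # nt between primary site end and cofactor start
    decoy: str | None = None        # low-complexity run planted in non-carriers
    signal_s0: float = 10.0
    signal_beta: float = 1.0
    signal_sigma: float = 0.5       # lognormal sigma (natural log)
    seed: int = 0


@dataclass
class PlantedSite:
    peak_id: str
    kind: str      # primary | cofactor | decoy
    start: int
    end: int
    strand: str
    gap: int | None = None


@dataclass
class GroundTruth:
    spec: SimSpec
    sites: list[PlantedSite]
    primary_fm: FrequencyMatrix | None
    left_fm: FrequencyMatrix | None = None
    right_fm: FrequencyMatrix | None = None

    def sites_of(self, kind: str) -> list[PlantedSite]:
        return [s for s in self.sites if s.kind == kind]

    def generating_ipwm(self, n: int) -> InformationWeightMatrix:
        """iPWM of the generating frequency matrix at site count n, for
        distance comparisons with recovered models."""
        fm = FrequencyMatrix(self.primary_fm.freqs, n=n)
        return build_ipwm(fm)

    def generating_half_ipwms(self, n: int):
        left = build_ipwm(FrequencyMatrix(self.left_fm.freqs, n=n))
        right = build_ipwm(FrequencyMatrix(self.right_fm.freqs, n=n))
        return left, right

    def to_json(self, path) -> None:
        payload = {
            "sites": [
                {"peak_id": s.peak_id, "kind": s.kind, "start": s.start,
                 "end": s.end, "strand": s.strand, "gap": s.gap}
                for s in self.sites
            ],
            "primary_freqs": None if self.primary_fm is None
            else self.primary_fm.freqs.tolist(),
            "left_freqs": None if self.left_fm is None else self.left_fm.freqs.tolist(),
            "right_freqs": None if self.right_fm is None else self.right_fm.freqs.tolist(),
            "seed": self.spec.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# dataset generation


def _random_background(rng, length: int, bg: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=length, p=bg)


def generate_peak_dataset(spec: SimSpec) -> tuple[PeakDataset, GroundTruth]:
    """Build a ranked peak dataset per the spec, with serializable ground
    truth (planted site coordinates, spacers and generating matrices)."""
    rng = np.random.default_rng(spec.seed)
    bipartite_mode = spec.left is not None
    if bipartite_mode:
        if spec.right is None or spec.gap_distribution is None:
            raise ValueError("bipartite generation needs left, right and gap_distribution")
        max_span = spec.left.length + spec.gap_min + len(spec.gap_distribution) - 1 \
            + spec.right.length
        score_model = None
    elif spec.primary is not None:
        max_span = spec.primary.length
        # asymptotic iPWM of the generator, for signal coupling
        score_model = build_ipwm(FrequencyMatrix(spec.primary.freqs, n=10_000))
    else:
        max_span = 0
        score_model = None
    if max_span > spec.peak_length:
        raise ValueError("site span exceeds peak length")
    if spec.cofactor is not None and spec.cofactor.length > spec.peak_length:
        raise ValueError("cofactor span exceeds peak length")

    n = spec.n_peaks
    if spec.n_carriers is not None:
        carriers = np.arange(n) < spec.n_carriers
    else:
        carriers = rng.random(n) < spec.carrier_fraction
    seqs: list[str] = []
    planted: list[tuple] = []   # (index, kind, start, end, strand, gap)
    ri_values = np.zeros(n)
    for i in range(n):
        codes = _random_background(rng, spec.peak_length, spec.background)
        seq = "".join(ALPHABET[c] for c in codes)
        if carriers[i] and max_span > 0:
            if bipartite_mode:
                sites, gaps = generate_bipartite_sites(
                    spec.left, spec.right, spec.gap_distribution, spec.gap_min,
                    1, rng, spec.background,
                )
                site, gap = sites[0], int(gaps[0])
            else:
                site, gap = sample_sites(spec.primary, 1, rng)[0], None
            strand = "+" if rng.random() < 0.5 else "-"
            placed = site if strand == "+" else revcomp(site)
            start = int(rng.integers(0, spec.peak_length - len(placed) + 1))
            seq = seq[:start] + placed + seq[start + len(placed):]
            planted.append((i, "primary", start, start + len(placed), strand, gap))
            if score_model is not None:
                ri_values[i] = score_site(score_model, site, 0, "+")
            if spec.cofactor is not None and rng.random() < spec.cofactor_fraction:
                csite = sample_sites(spec.cofactor, 1, rng)[0]
                # downstream of the primary site, or upstream if it won't fit
                cstart = start + len(placed) + spec.cofactor_distance
                if cstart + len(csite) > spec.peak_length:
                    cstart = start - spec.cofactor_distance - len(csite)
                if 0 <= cstart and cstart + len(csite) <= spec.peak_length:
                    seq = seq[:cstart] + csite + seq[cstart + len(csite):]
                    planted.append((i, "cofactor", cstart, cstart + len(csite), "+", None))
        elif not carriers[i] and spec.decoy:
            start = int(rng.integers(0, spec.peak_length - len(spec.decoy) + 1))
            seq = seq[:start] + spec.decoy + seq[start + len(spec.decoy):]
            planted.append((i, "decoy", start, start + len(spec.decoy), "+", None))
        seqs.append(seq)

    # signal model: s0 * 2^(beta * Ri) * lognormal noise
    noise = rng.lognormal(mean=0.0, sigma=spec.signal_sigma, size=n)
    signals = spec.signal_s0 * (2.0 ** (spec.signal_beta * ri_values)) * noise
    if spec.carriers_on_top:
        # carriers take the largest signals (rank-confined motif placement);
        # relative order within each group is preserved
        order = np.argsort(-signals, kind="stable")
        sorted_signals = signals[order]
        idx_carriers = np.flatnonzero(carriers)
        idx_rest = np.flatnonzero(~carriers)
        new = np.empty(n)
        new[idx_carriers] = sorted_signals[: len(idx_carriers)]
        new[idx_rest] = sorted_signals[len(idx_carriers):]
        signals = new

    peaks = [
        Peak(chrom=f"peak_{i:05d}", start=0, end=spec.peak_length,
             signal=float(signals[i]), sequence=seqs[i])
        for i in range(n)
    ]
    ds = PeakDataset.from_peaks(peaks, source=f"synthetic(seed={spec.seed})")
    truth_sites = [
        PlantedSite(f"peak_{i:05d}", kind, start, end, strand, gap)
        for (i, kind, start, end, strand, gap) in planted
    ]
    truth = GroundTruth(
        spec=spec,
        sites=truth_sites,
        primary_fm=spec.primary,
        left_fm=spec.left,
        right_fm=spec.right,
    )
    return ds, truth
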