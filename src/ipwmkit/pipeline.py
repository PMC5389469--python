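"""Orchestration: rank-threshold refinement, motif classification and the
full threshold+mask discovery loop over ranked peak datasets.

Weak ChIP-seq peaks contribute low-complexity sequence that can outcompete
the true binding motif in entropy minimization, so discovery is run on the
largest top-rank prefix that still yields the motif.  That prefix is found
by a half-interval search over peak-strength thresholds: with G the current
(greater) threshold and S the smaller bound, a midpoint prefix M (rounded to
a multiple of 500 peaks) is tested by deriving its iPWM and asking whether
it is closer, in normalized Euclidean distance, to the motif model at G or
the (noise-contaminated) model at S.  The bracket narrows until it holds at
most 500 peaks; the returned threshold is the final G.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import (
    MaskSet,
    SearchResult,
    minimize_entropy,
    recursive_discover,
)
from .information import AlignedSites, Model, euclidean_distance
from .io_formats import PeakDataset
from .patterns import SearchPattern
from .validation import RegressionResult, ri_energy_ftest

logger = logging.getLogger(__name__)


@dataclass
class SearchSettings:
    """Budget for each model derivation inside the threshold search."""

    cycles: int = 2
    patience: int = 8
    max_sweeps: int = 40


# ---------------------------------------------------------------------------
# motif vs noise classification


@dataclass
class Classification:
    accept: bool
    rsequence_per_nt: float
    regression: RegressionResult | None
    reason: str = ""


def training_site_ri(model: Model, alignment: AlignedSites) -> np.ndarray:
    """Ri of every included training site under the derived model."""
    mat = alignment.site_codes()
    w = model.weights
    return w[mat, np.arange(w.shape[1])[None, :]].sum(axis=1)


def classify_motif(
    model: Model,
    alignment: AlignedSites,
    signals: np.ndarray,
    *,
    rseq_floor: float = 0.5,
    f_threshold: float = 1000.0,
    min_sites: int = 50,
) -> Classification:
    """Accept a model as a true motif, or reject it as noise.

    Accept requires (i) overall conservation Rsequence/L of at least
    ``rseq_floor`` bits/nt, and (ii) the Ri-vs-binding-energy regression over
    the training sites to have negative slope with F above ``f_threshold`` —
    noise motifs show no Ri-signal relationship regardless of how conserved
    (e.g. poly-A runs) they are.
    """
    if alignment.n_included < min_sites:
        raise ValueError(f"classification needs >= {min_sites} training sites")
    ri = training_site_ri(model, alignment)
    sig = np.asarray(signals, dtype=float)[alignment.included]
    rseq_nt = model.rsequence_per_nt
    if rseq_nt < rseq_floor:
        return Classification(False, rseq_nt, None, "conservation below floor")
    try:
        reg = ri_energy_ftest(ri, sig)
    except ValueError as exc:
        return Classification(False, rseq_nt, None, f"regression undefined: {exc}")
    if reg.slope < 0 and reg.F > f_threshold:
        return Classification(True, rseq_nt, reg, "accepted")
    return Classification(False, rseq_nt, reg, "no Ri-energy relationship")


def make_reference_classifier(reference: Model, max_distance: float = 1.0):
    """Benchmark-mode classifier: accept iff the model is within
    ``max_distance`` bits/nt of a supplied reference matrix."""

    def classify(model: Model, ds: PeakDataset | None = None,
                 alignment: AlignedSites | None = None) -> bool:
        return euclidean_distance(model, reference) < max_distance

    return classify


def make_statistical_classifier(**kwargs):
    """Classifier closure over :func:`classify_motif` for pipeline use."""

    def classify(model: Model, ds: PeakDataset, alignment: AlignedSites) -> bool:
        return classify_motif(model, alignment, ds.signals(), **kwargs).accept

    return classify


# ---------------------------------------------------------------------------
# half-interval threshold search


@dataclass
class BracketStep:
    n_G: int
    n_S: int
    m: int
    d_GM: float
    d_SM: float
    moved: str  # "S->M" (M was motif side) or "G->M" (M was noise side)


@dataclass
class ThresholdSearchResult:
    status: str                    # ok | no-motif-in-top-200 | search-skipped
    G: float | None = None         # final threshold signal strength
    n_G: int = 0                   # peaks at or above the final threshold
    n_S: int = 0
    model: Model | None = None
    result: SearchResult | None = None
    trace: list[BracketStep] = field(default_factory=list)

    @property
    def bracket_width(self) -> int:
        return self.n_S - self.n_G


def _derivation_seed(seed: int, m: int) -> int:
    return int(np.random.SeedSequence([seed, m]).generate_state(1)[0] % (2**31))


def threshold_search(
    ds: PeakDataset,
    pattern: SearchPattern,
    classify,
    seed: int = 0,
    *,
    settings: SearchSettings | None = None,
    init_top: int = 200,
    step: int = 500,
    stop_width: int = 500,
) -> ThresholdSearchResult:
    """Half-interval search for the largest top-peak prefix yielding the motif.

    ``classify(model, prefix_dataset, alignment) -> bool`` judges the
    top-``init_top`` model; bracket moves are decided purely by matrix
    distances (the midpoint model joins whichever endpoint it resembles).
    Endpoint models are derived once, with a fixed per-prefix seed, and
    reused as the bracket moves.  Datasets smaller than ``init_top`` skip
    the search and return the whole-dataset model.
    """
    settings = settings or SearchSettings()
    N = len(ds)
    cache: dict[int, SearchResult] = {}

    def derive(m: int) -> SearchResult:
        if m not in cache:
            prefix = ds.top(m)
            cache[m] = minimize_entropy(
                prefix.sequences(), pattern,
                cycles=settings.cycles, seed=_derivation_seed(seed, m),
                patience=settings.patience, max_sweeps=settings.max_sweeps,
            )
        return cache[m]

    if N < init_top:
        res = derive(N)
        return ThresholdSearchResult(
            status="search-skipped", G=ds.peaks[-1].signal, n_G=N, n_S=N,
            model=res.model, result=res,
        )

    res_G = derive(init_top)
    if not classify(res_G.model, ds.top(init_top), res_G.alignment):
        return ThresholdSearchResult(status="no-motif-in-top-200")

    n_G, n_S = init_top, N
    model_G, model_S = res_G.model, derive(N).model
    trace: list[BracketStep] = []
    while n_S - n_G > stop_width:
        mean = (n_G + n_S) / 2.0
        m = int(np.floor(mean / step + 0.5)) * step  # round half up
        lo, hi = n_G + step, n_S - step
        if lo <= hi:
            m = min(max(m, lo), hi)
        else:
            # no multiple-of-step point with full clearance; take any
            # multiple strictly inside the bracket to guarantee progress
            inside = [k * step for k in range(n_G // step + 1, -(-n_S // step))
                      if n_G < k * step < n_S]
            if not inside:
                break
            m = min(inside, key=lambda k: abs(k - mean))
        res_M = derive(m)
        d_GM = euclidean_distance(model_G, res_M.model)
        d_SM = euclidean_distance(model_S, res_M.model)
        if d_GM > d_SM:
            # midpoint resembles the noise end: threshold is above M
            trace.append(BracketStep(n_G, n_S, m, d_GM, d_SM, "S->M"))
            n_S, model_S = m, res_M.model
        else:
            trace.append(BracketStep(n_G, n_S, m, d_GM, d_SM, "G->M"))
            n_G, model_G = m, res_M.model
        logger.info(
            "bracket [%d, %d] after testing m=%d (d_GM=%.3f, d_SM=%.3f)",
            n_G, n_S, m, d_GM, d_SM,
        )
    final = derive(n_G)
    return ThresholdSearchResult(
        status="ok", G=ds.peaks[n_G - 1].signal, n_G=n_G, n_S=n_S,
        model=final.model, result=final, trace=trace,
    )


# ---------------------------------------------------------------------------
# full discovery run


@dataclass
class DiscoveryConfig:
    seed: int = 0
    cycles: int = 5
    site_threshold: float = 0.0     # Ri > 0 marks a potentially functional site
    max_cofactor_rounds: int = 2
    rseq_floor: float = 0.5
    f_threshold: float = 1000.0
    min_sites: int = 50
    mask_flank: int = 0
    threshold_settings: SearchSettings = field(default_factory=SearchSettings)


@dataclass
class PatternOutcome:
    pattern: SearchPattern
    primary: SearchResult
    classification: Classification
    threshold: ThresholdSearchResult | None
    prefix_size: int
    cofactors: list[SearchResult]


@dataclass
class DiscoveryRun:
    outcomes: list[PatternOutcome]
    manifest: dict

    @property
    def accepted_models(self) -> list[Model]:
        out = []
        for oc in self.outcomes:
            if oc.classification.accept:
                out.append(oc.primary.model)
            out.extend(r.model for r in oc.cofactors if r.accepted)
        return out


def run_discovery(
    ds: PeakDataset,
    patterns: list[SearchPattern],
    config: DiscoveryConfig | None = None,
) -> DiscoveryRun:
    """The full pipeline for each search pattern: initial entropy
    minimization on all peaks; if the model classifies as noise, the
    threshold search restricts to the strongest peaks; recursive masked
    rediscovery then surfaces cofactor motifs.  A pure-noise dataset yields
    zero accepted models without error."""
    from . import __version__

    config = config or DiscoveryConfig()
    outcomes: list[PatternOutcome] = []
    for p_idx, pattern in enumerate(patterns):
        seed_p = _derivation_seed(config.seed, 7_000_000 + p_idx)
        res = minimize_entropy(
            ds.sequences(), pattern, cycles=config.cycles, seed=seed_p
        )
        cls = classify_motif(
            res.model, res.alignment, ds.signals(),
            rseq_floor=config.rseq_floor, f_threshold=config.f_threshold,
            min_sites=config.min_sites,
        )
        ts = None
        work_ds, primary, prefix_size = ds, res, len(ds)
        if not cls.accept:
            ts = threshold_search(
                ds, pattern,
                make_statistical_classifier(
                    rseq_floor=config.rseq_floor,
                    f_threshold=config.f_threshold,
                    min_sites=config.min_sites,
                ),
                seed=_derivation_seed(config.seed, 9_000_000 + p_idx),
                settings=config.threshold_settings,
            )
            if ts.status == "ok":
                work_ds, primary, prefix_size = ds.top(ts.n_G), ts.result, ts.n_G
                cls = classify_motif(
                    primary.model, primary.alignment, work_ds.signals(),
                    rseq_floor=config.rseq_floor, f_threshold=config.f_threshold,
                    min_sites=config.min_sites,
                )
        cofactors: list[SearchResult] = []
        if cls.accept:
            # mask the primary's training sites, then search for cofactors
            sites = []
            from .scanning import ScanConfig, scan_sequence

            cfg = ScanConfig(threshold=config.site_threshold, overlap="best-per-window")
            seqs = work_ds.sequences()
            base_mask = MaskSet()
            for i, s in enumerate(seqs):
                for site in scan_sequence(primary.model, s, cfg, seq_id=str(i)):
                    base_mask.add(i, max(0, site.start - config.mask_flank),
                                  site.end + config.mask_flank)
            signals = work_ds.signals()

            def cof_classifier(r: SearchResult) -> bool:
                try:
                    return classify_motif(
                        r.model, r.alignment, signals,
                        rseq_floor=config.rseq_floor,
                        f_threshold=config.f_threshold,
                        min_sites=config.min_sites,
                    ).accept
                except ValueError:
                    return False

            cofactors = recursive_discover(
                seqs, pattern, max_rounds=config.max_cofactor_rounds,
                site_threshold=config.site_threshold,
                classifier=cof_classifier, cycles=config.cycles,
                seed=_derivation_seed(config.seed, 11_000_000 + p_idx),
                mask=base_mask,
            )
        outcomes.append(
            PatternOutcome(pattern, primary, cls, ts, prefix_size, cofactors)
        )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "cycles": config.cycles,
        "site_threshold": config.site_threshold,
        "rseq_floor": config.rseq_floor,
        "f_threshold": config.f_threshold,
        "patterns": [str(p) for p in patterns],
        "n_peaks": len(ds),
        "source": ds.source,
    }
    return DiscoveryRun(outcomes=outcomes, manifest=manifest)
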