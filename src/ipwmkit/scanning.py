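"""Locate and score binding sites of a model across sequences or peak sets.

Every window on the requested strands is scored (bipartite models enumerate
every spacer length in the pattern's range, not only the dominant one — real
site populations spread across the full range); windows containing N are
skipped.  Per-peak scans always record the best site even when it falls
below the reporting threshold, which is what the Ri-vs-signal regression of
the noise classifier needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .information import (
    BindingSite,
    BipartiteModel,
    InformationWeightMatrix,
    Model,
)
from .io_formats import PeakDataset
from .seq import decode, encode, revcomp_codes


@dataclass
class ScanConfig:
    threshold: float = 0.0        # minimum Ri (bits) to report
    strands: str = "both"         # "both" | "forward"
    overlap: str = "report-all"   # "report-all" | "best-per-window"

    def __post_init__(self) -> None:
        if np.isnan(self.threshold):
            raise ValueError("threshold must not be NaN")
        if self.strands not in ("both", "forward"):
            raise ValueError("strands must be 'both' or 'forward'")
        if self.overlap not in ("report-all", "best-per-window"):
            raise ValueError("overlap must be 'report-all' or 'best-per-window'")


def _window_scores(weights: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Ri of every window of len(weights) columns; NaN where a window has N."""
    L = weights.shape[1]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    idx = np.arange(n_win)[:, None] + np.arange(L)[None, :]
    wins = codes[idx]
    valid = np.all(wins < 4, axis=1)
    safe = np.where(wins < 4, wins, 0)
    scores = weights[safe, np.arange(L)[None, :]].sum(axis=1)
    scores[~valid] = np.nan
    return scores


def window_scores(model: Model, codes: np.ndarray, strands: str = "both"):
    """Score every scorable placement at once.

    Returns parallel arrays ``(starts, spans, minus, gaps, scores)``;
    windows containing N are dropped.
    """
    strand_list = ["+"] if strands == "forward" else ["+", "-"]
    n = len(codes)
    if isinstance(model, InformationWeightMatrix):
        spans = [(0, model.length, model.weights, 0.0)]
    else:
        pat = model.pattern
        spans = []
        for gap in range(pat.gap_min, pat.gap_max + 1):
            # weights with uninformative spacer columns inserted: spacer
            # bases get zero weight so a single gather scores the full span
            w = np.zeros((4, pat.span(gap)))
            w[:, : pat.left] = model.left.weights
            w[:, pat.left + gap :] = model.right.weights
            extra = model.gap_information(gap) if model.include_gap_information else 0.0
            spans.append((gap, pat.span(gap), w, extra))
    out_start, out_span, out_minus, out_gap, out_score = [], [], [], [], []
    for strand in strand_list:
        sc = codes if strand == "+" else revcomp_codes(codes)
        for gap, span, w, extra in spans:
            scores = _window_scores(w, sc)
            valid = ~np.isnan(scores)
            if not np.any(valid):
                continue
            idx = np.flatnonzero(valid)
            starts = idx if strand == "+" else n - idx - span
            out_start.append(starts)
            out_span.append(np.full(len(idx), span))
            out_minus.append(np.full(len(idx), strand == "-"))
            out_gap.append(np.full(len(idx), gap))
            out_score.append(scores[idx] + extra)
    if not out_start:
        empty = np.empty(0, dtype=int)
        return empty, empty, np.empty(0, bool), empty, np.empty(0)
    return (
        np.concatenate(out_start),
        np.concatenate(out_span),
        np.concatenate(out_minus),
        np.concatenate(out_gap),
        np.concatenate(out_score),
    )


def _make_site(model, codes, seq_id, start, span, minus, gap, ri) -> BindingSite:
    window = codes[start : start + span]
    if minus:
        window = revcomp_codes(window)
    return BindingSite(
        seq_id, int(start), int(start + span), "-" if minus else "+",
        float(ri), decode(window),
        int(gap) if isinstance(model, BipartiteModel) else None,
    )


def scan_sequence(
    model: Model, seq: str, cfg: ScanConfig | None = None, seq_id: str = "seq"
) -> list[BindingSite]:
    """All binding sites with Ri >= threshold, sorted by start coordinate.

    Under ``best-per-window``, among sites sharing a start only the max-Ri
    one is kept (ties prefer the + strand, then the smaller gap).
    """
    cfg = cfg or ScanConfig()
    codes = encode(seq)
    starts, spans, minus, gaps, scores = window_scores(model, codes, cfg.strands)
    keep = scores >= cfg.threshold
    hits = [
        _make_site(model, codes, seq_id, starts[i], spans[i], minus[i], gaps[i],
                   scores[i])
        for i in np.flatnonzero(keep)
    ]
    if cfg.overlap == "best-per-window":
        best: dict[int, BindingSite] = {}
        for s in hits:
            cur = best.get(s.start)
            if cur is None or _site_order_key(s) < _site_order_key(cur):
                best[s.start] = s
        hits = list(best.values())
    hits.sort(key=lambda s: (s.start, s.strand, s.gap if s.gap is not None else -1))
    return hits


def _site_order_key(s: BindingSite):
    # max Ri first; ties: + strand, then smaller gap
    return (-s.ri, 0 if s.strand == "+" else 1, s.gap if s.gap is not None else 0)


@dataclass
class PeakScan:
    """Best site of one peak (always recorded, even below threshold)."""

    rank: int
    signal: float
    best: BindingSite | None   # None when no window was scorable (e.g. all N)
    passed: bool               # best.ri >= threshold


@dataclass
class DatasetScan:
    sites: list[BindingSite] = field(default_factory=list)
    per_peak: list[PeakScan] = field(default_factory=list)

    def best_ri(self) -> np.ndarray:
        return np.array([p.best.ri for p in self.per_peak if p.best is not None])

    def best_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(Ri, signal) of each peak's best site, for the energy regression."""
        pairs = [(p.best.ri, p.signal) for p in self.per_peak if p.best is not None]
        if not pairs:
            return np.empty(0), np.empty(0)
        ri, sig = zip(*pairs)
        return np.array(ri), np.array(sig)


def scan_dataset(model: Model, ds: PeakDataset, cfg: ScanConfig | None = None) -> DatasetScan:
    """Scan every peak; thresholded site list plus per-peak best sites."""
    cfg = cfg or ScanConfig()
    out = DatasetScan()
    for p in ds.peaks:
        codes = encode(p.sequence)
        starts, spans, minus, gaps, scores = window_scores(model, codes, cfg.strands)
        if len(scores) == 0:
            out.per_peak.append(PeakScan(p.rank, p.signal, None, False))
            continue
        # best site: max Ri, ties prefer + strand then smaller gap
        order = np.lexsort((gaps, minus, -scores))
        b = order[0]
        best = _make_site(model, codes, p.chrom, starts[b], spans[b], minus[b],
                          gaps[b], scores[b])
        out.per_peak.append(
            PeakScan(p.rank, p.signal, best, bool(best.ri >= cfg.threshold))
        )
        for i in np.flatnonzero(scores >= cfg.threshold):
            s = _make_site(model, codes, p.chrom, starts[i], spans[i], minus[i],
                           gaps[i], scores[i])
            s.rank = p.rank
            out.sites.append(s)
    out.sites.sort(key=lambda s: (s.seq_id, s.start, s.strand,
                                  s.gap if s.gap is not None else -1))
    if cfg.overlap == "best-per-window":
        # collapse per start coordinate within each peak
        collapsed: dict[tuple, BindingSite] = {}
        for s in out.sites:
            key = (s.seq_id, s.start)
            cur = collapsed.get(key)
            if cur is None or _site_order_key(s) < _site_order_key(cur):
                collapsed[key] = s
        out.sites = sorted(
            collapsed.values(), key=lambda s: (s.seq_id, s.start, s.strand)
        )
    return out
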