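"""Monte-Carlo entropy minimization: the lowest-entropy multiple local
alignment of one site per sequence, contiguous or bipartite, with masking.

The objective is the mean Shannon entropy (bits/position) of the alignment
columns; for bipartite patterns the entropy of the spacer-length
distribution, divided by the number of matrix columns, is added so the
optimizer is rewarded for concentrating spacers on a preferred length.
Minimizing entropy maximizes the information content of the resulting iPWM
and, unlike likelihood-based mixture models, needs no background
composition model — the lowest-entropy motif wins regardless of skewed
genomic composition.

The search is a Gibbs sampler: each sequence's site placement (offset,
strand and, for bipartite patterns, spacer) is resampled from the
Boltzmann-like distribution implied by the column counts with that sequence
held out, at unit temperature.  Independent restarts guard against local
optima and a deterministic coordinate-descent polish (each sequence moved to
its exactly-best placement until no move helps) finishes at a local minimum
of the true objective.  Masked intervals are never sampled, which is what
makes recursive discovery of cofactor motifs possible: mask the sites of the
motifs already found, rerun, and the next-lowest-entropy motif emerges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .information import (
    AlignedSites,
    BindingSite,
    Model,
    PSEUDOCOUNT,
    GAP_PSEUDOCOUNT,
    ipwm_from_sites,
)
from .patterns import SearchPattern
from .seq import encode, revcomp_codes

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# masks


class MaskSet:
    """Per-sequence intervals (0-based half-open) excluded from placement."""

    def __init__(self) -> None:
        self.intervals: dict = {}

    def add(self, key, start: int, end: int) -> None:
        if end <= start:
            return
        merged = []
        placed = False
        for s, e in self.intervals.get(key, []):
            if e < start or s > end:
                merged.append((s, e))
            else:
                start, end = min(s, start), max(e, end)
        merged.append((start, end))
        self.intervals[key] = sorted(merged)

    def get(self, key) -> list[tuple[int, int]]:
        return self.intervals.get(key, [])

    def overlaps(self, key, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.get(key))

    def update(self, other: "MaskSet") -> None:
        for key, ivs in other.intervals.items():
            for s, e in ivs:
                self.add(key, s, e)

    def forbidden_array(self, key, length: int) -> np.ndarray:
        arr = np.zeros(length, dtype=bool)
        for s, e in self.get(key):
            arr[max(0, s) : min(length, e)] = True
        return arr

    def __len__(self) -> int:
        return sum(len(v) for v in self.intervals.values())


def mask_from_sites(
    sites: list[BindingSite], flank: int = 0, seq_lengths: dict | None = None
) -> MaskSet:
    """One mask interval per site, widened by ``flank`` nt and clipped to the
    sequence bounds; overlapping intervals merge."""
    mask = MaskSet()
    for s in sites:
        start = max(0, s.start - flank)
        end = s.end + flank
        if seq_lengths is not None and s.seq_id in seq_lengths:
            end = min(end, seq_lengths[s.seq_id])
        mask.add(s.seq_id, start, end)
    return mask


# ---------------------------------------------------------------------------
# candidate placements


@dataclass
class _Candidates:
    """All legal placements for one sequence, in motif orientation."""

    bases: np.ndarray    # (C, W) int8, spacer removed, revcomp'd for '-'
    starts: np.ndarray   # (C,) original-coordinate window starts
    strands: np.ndarray  # (C,) '+'/'-'
    gaps: np.ndarray     # (C,) spacer length (0 for contiguous)
    spans: np.ndarray    # (C,) genomic footprint


def _build_candidates(
    codes: np.ndarray, pattern: SearchPattern, forbidden: np.ndarray | None,
    strands: str = "both",
) -> _Candidates:
    n = len(codes)
    rc = revcomp_codes(codes)
    if forbidden is None:
        cum = None
    else:
        cum = np.concatenate([[0], np.cumsum(forbidden)])
    gap_range = (
        range(pattern.gap_min, pattern.gap_max + 1)
        if pattern.kind == "bipartite"
        else [0]
    )
    cols_parts, all_bases, all_starts, all_strands, all_gaps, all_spans = (
        None, [], [], [], [], [],
    )
    strand_list = ["+"] if strands == "forward" else ["+", "-"]
    for gap in gap_range:
        span = pattern.span(gap) if pattern.kind == "bipartite" else pattern.left
        n_off = n - span + 1
        if n_off <= 0:
            continue
        if pattern.kind == "bipartite":
            col_idx = np.concatenate(
                [np.arange(pattern.left), pattern.left + gap + np.arange(pattern.right)]
            )
        else:
            col_idx = np.arange(pattern.left)
        for strand in strand_list:
            src = codes if strand == "+" else rc
            offs = np.arange(n_off)
            bases = src[offs[:, None] + col_idx[None, :]]
            starts = offs if strand == "+" else n - offs - span
            ok = np.all(bases < 4, axis=1)
            if cum is not None:
                ok &= (cum[starts + span] - cum[starts]) == 0
            if not np.any(ok):
                continue
            all_bases.append(bases[ok])
            all_starts.append(starts[ok])
            all_strands.append(np.full(ok.sum(), strand))
            all_gaps.append(np.full(ok.sum(), gap))
            all_spans.append(np.full(ok.sum(), span))
    if not all_bases:
        return _Candidates(
            np.empty((0, pattern.width), dtype=np.int8), np.empty(0, int),
            np.empty(0, "<U1"), np.empty(0, int), np.empty(0, int),
        )
    return _Candidates(
        np.concatenate(all_bases).astype(np.int8),
        np.concatenate(all_starts),
        np.concatenate(all_strands),
        np.concatenate(all_gaps),
        np.concatenate(all_spans),
    )


# ---------------------------------------------------------------------------
# objective


def _entropy_of_counts(counts: np.ndarray, total: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        f = counts / total
        return np.where(f > 0, -f * np.log2(np.where(f > 0, f, 1.0)), 0.0)


def objective_entropy(
    sites: AlignedSites, include_gap_entropy: bool = True
) -> float:
    """Mean column entropy of the alignment in bits/position (+ spacer-length
    entropy spread over the matrix columns, for bipartite patterns)."""
    if sites.n_included < 2:
        raise ValueError("objective needs at least 2 included sites")
    mat = sites.site_codes()
    n, W = mat.shape
    counts = np.zeros((4, W))
    for b in range(4):
        counts[b] = (mat == b).sum(axis=0)
    obj = float(_entropy_of_counts(counts, n).sum(axis=0).mean())
    if sites.pattern.kind == "bipartite" and include_gap_entropy:
        hist = sites.gap_histogram().astype(float)
        obj += float(_entropy_of_counts(hist, hist.sum()).sum()) / W
    return obj


# ---------------------------------------------------------------------------
# search


@dataclass
class SearchResult:
    model: Model
    alignment: AlignedSites
    objective: float
    cycles: int
    seed: int
    n_excluded: int = 0
    accepted: bool | None = None
    round: int | None = None


class _State:
    """Mutable alignment state over precomputed candidates."""

    def __init__(self, cands: list[_Candidates], pattern: SearchPattern):
        self.cands = cands
        self.pattern = pattern
        self.active = [i for i, c in enumerate(cands) if len(c.starts) > 0]
        self.W = pattern.width
        self.n_gaps = pattern.n_gaps
        self.choice = np.zeros(len(cands), dtype=int)
        self.counts = np.zeros((4, self.W))
        self.gap_counts = np.zeros(self.n_gaps)
        self._cols = np.arange(self.W)
        # sorted numeric keys per sequence for O(log C) placement lookup
        self._keys: list[tuple[np.ndarray, np.ndarray]] = []
        for c in cands:
            key = self._placement_key(c.starts, c.strands == "-", c.gaps)
            order = np.argsort(key)
            self._keys.append((key[order], order))

    def _placement_key(self, start, minus, gap) -> np.ndarray:
        g = np.asarray(gap) - self.pattern.gap_min
        return (np.asarray(start) * 2 + np.asarray(minus)) * self.n_gaps + g

    def _lookup(self, i: int, start: int, minus: bool, gap: int) -> int | None:
        if start < 0 or not (
            self.pattern.gap_min <= gap <= self.pattern.gap_max
            or self.pattern.kind == "contiguous"
        ):
            return None
        keys, order = self._keys[i]
        key = int((start * 2 + int(minus)) * self.n_gaps + (gap - self.pattern.gap_min))
        pos = int(np.searchsorted(keys, key))
        if pos < len(keys) and keys[pos] == key:
            return int(order[pos])
        return None

    def init_random(self, rng: np.random.Generator) -> None:
        self.counts[:] = 0.0
        self.gap_counts[:] = 0.0
        for i in self.active:
            self.choice[i] = rng.integers(len(self.cands[i].starts))
            self._apply(i, +1)

    def set_choices(self, choice: np.ndarray) -> None:
        self.counts[:] = 0.0
        self.gap_counts[:] = 0.0
        self.choice = choice.copy()
        for i in self.active:
            self._apply(i, +1)

    def _apply(self, i: int, sign: int) -> None:
        c = self.cands[i]
        k = self.choice[i]
        np.add.at(self.counts, (c.bases[k], self._cols), sign)
        if self.pattern.kind == "bipartite":
            self.gap_counts[c.gaps[k] - self.pattern.gap_min] += sign

    def objective(self, include_gap_entropy: bool) -> float:
        n = len(self.active)
        obj = float(_entropy_of_counts(self.counts, n).sum(axis=0).mean())
        if self.pattern.kind == "bipartite" and include_gap_entropy:
            obj += float(_entropy_of_counts(self.gap_counts, n).sum()) / self.W
        return obj

    def gibbs_sweep(self, rng: np.random.Generator, include_gap_entropy: bool) -> None:
        order = rng.permutation(self.active)
        for i in order:
            c = self.cands[i]
            if len(c.starts) == 1:
                continue
            self._apply(i, -1)
            logf = np.log(self.counts + PSEUDOCOUNT)
            logp = logf[c.bases, self._cols[None, :]].sum(axis=1)
            if self.pattern.kind == "bipartite" and include_gap_entropy:
                logg = np.log(self.gap_counts + GAP_PSEUDOCOUNT)
                logp = logp + logg[c.gaps - self.pattern.gap_min]
            logp -= logp.max()
            p = np.exp(logp)
            p /= p.sum()
            self.choice[i] = rng.choice(len(p), p=p)
            self._apply(i, +1)

    def polish(self, include_gap_entropy: bool, max_passes: int = 5) -> None:
        """Exact coordinate descent on the objective until a local minimum."""
        n = len(self.active)
        for _ in range(max_passes):
            moved = False
            for i in self.active:
                c = self.cands[i]
                if len(c.starts) == 1:
                    continue
                self._apply(i, -1)
                # entropy of each column after adding one base of each kind
                A = np.repeat(self.counts[:, None, :], 4, axis=1)
                A[np.arange(4), np.arange(4), :] += 1
                h_add = _entropy_of_counts(A, n).sum(axis=0)  # (4, W)
                obj = h_add[c.bases, self._cols[None, :]].sum(axis=1) / self.W
                if self.pattern.kind == "bipartite" and include_gap_entropy:
                    G = np.repeat(self.gap_counts[:, None], self.n_gaps, axis=1)
                    G[np.arange(self.n_gaps), np.arange(self.n_gaps)] += 1
                    hg = _entropy_of_counts(G, n).sum(axis=0)  # (n_gaps,)
                    obj = obj + hg[c.gaps - self.pattern.gap_min] / self.W
                k = int(np.argmin(obj))
                if obj[k] < obj[self.choice[i]] - 1e-12:
                    self.choice[i] = k
                    moved = True
                self._apply(i, +1)
            if not moved:
                break


_PHASE_MOVES_CONTIG = [(-2, -2), (-1, -1), (1, 1), (2, 2)]
_PHASE_MOVES_BIPART = [
    (dl, dr) for dl in (-1, 0, 1) for dr in (-1, 0, 1) if (dl, dr) != (0, 0)
] + [(-2, -2), (2, 2)]


def _phase_moves(pattern: SearchPattern):
    return _PHASE_MOVES_CONTIG if pattern.kind == "contiguous" else _PHASE_MOVES_BIPART


def _try_phase_moves(state: _State, include_gap_entropy: bool) -> bool:
    """Propose shifting the whole alignment register.

    Gibbs samplers over site placements converge readily to phase-shifted
    optima (every site moved one base, half-site boundaries slid into the
    spacer) because single-sequence updates cannot cross between phases.
    Each move slides the left and right motif edges by (dl, dr) in motif
    orientation for every sequence where the shifted placement is legal;
    the best move is adopted if it lowers the objective.
    """
    base = state.objective(include_gap_entropy)
    saved = state.choice.copy()
    best_obj, best_choice = base, None
    for dl, dr in _phase_moves(state.pattern):
        proposal = saved.copy()
        changed = False
        for i in state.active:
            c = state.cands[i]
            k = saved[i]
            start, gap = int(c.starts[k]), int(c.gaps[k])
            minus = c.strands[k] == "-"
            if not minus:
                new_start, new_gap = start + dl, gap + dr - dl
            else:
                new_start, new_gap = start - dr, gap + dr - dl
            j = state._lookup(i, new_start, minus, new_gap)
            if j is not None:
                proposal[i] = j
                changed = True
        if not changed:
            continue
        state.set_choices(proposal)
        obj = state.objective(include_gap_entropy)
        if obj < best_obj - 1e-12:
            best_obj, best_choice = obj, proposal.copy()
    if best_choice is None:
        state.set_choices(saved)
        return False
    state.set_choices(best_choice)
    return True


def minimize_entropy(
    seqs: list[str],
    pattern: SearchPattern,
    cycles: int = 5,
    mask: MaskSet | None = None,
    seed: int = 0,
    *,
    patience: int = 15,
    max_sweeps: int = 150,
    include_gap_entropy: bool = True,
    strands: str = "both",
) -> SearchResult:
    """Lowest-entropy alignment of one site per sequence.

    ``cycles`` independent restarts of the Gibbs sampler are run (each until
    ``patience`` sweeps pass without improvement, capped at ``max_sweeps``),
    each followed by a deterministic polish; the best alignment over all
    restarts is returned.  Fully reproducible given ``seed``.  Sequences
    with no legal placement (too short, all-N, or fully masked) are
    excluded with a logged count; if all are excluded an error is raised.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    codes = [encode(s) for s in seqs]
    cands = [
        _build_candidates(
            codes[i],
            pattern,
            mask.forbidden_array(i, len(codes[i])) if mask is not None else None,
            strands=strands,
        )
        for i in range(len(seqs))
    ]
    state = _State(cands, pattern)
    n_excluded = len(seqs) - len(state.active)
    if n_excluded:
        logger.info("excluded %d sequences with no legal placement", n_excluded)
    if len(state.active) == 0:
        raise ValueError("no sequence admits a legal site placement")

    ss = np.random.SeedSequence(seed)
    best_choice, best_obj = None, np.inf
    for child in ss.spawn(cycles):
        rng = np.random.default_rng(child)
        state.init_random(rng)
        local_best, local_choice, stall = np.inf, None, 0
        for _ in range(max_sweeps):
            state.gibbs_sweep(rng, include_gap_entropy)
            obj = state.objective(include_gap_entropy)
            if obj < local_best - 1e-12:
                local_best, local_choice, stall = obj, state.choice.copy(), 0
            else:
                stall += 1
                if stall >= patience:
                    break
        state.set_choices(local_choice)
        state.polish(include_gap_entropy)
        # escape phase-shifted registrations, then re-polish
        for _ in range(6):
            if not _try_phase_moves(state, include_gap_entropy):
                break
            state.polish(include_gap_entropy)
        obj = state.objective(include_gap_entropy)
        if obj < best_obj:
            best_obj, best_choice = obj, state.choice.copy()

    state.set_choices(best_choice)
    included = np.zeros(len(seqs), dtype=bool)
    included[state.active] = True
    offsets = np.zeros(len(seqs), dtype=int)
    strands_arr = np.full(len(seqs), "+")
    gaps = np.zeros(len(seqs), dtype=int)
    for i in state.active:
        c = cands[i]
        k = state.choice[i]
        offsets[i] = c.starts[k]
        strands_arr[i] = c.strands[k]
        gaps[i] = c.gaps[k]
    alignment = AlignedSites(
        sequences=list(seqs),
        pattern=pattern,
        offsets=offsets,
        strands=strands_arr,
        gaps=gaps if pattern.kind == "bipartite" else None,
        included=included,
    )
    objective = objective_entropy(alignment, include_gap_entropy)
    return SearchResult(
        model=ipwm_from_sites(alignment),
        alignment=alignment,
        objective=objective,
        cycles=cycles,
        seed=seed,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# recursive discovery


def recursive_discover(
    seqs: list[str],
    pattern: SearchPattern,
    max_rounds: int = 3,
    site_threshold: float = 0.0,
    *,
    classifier=None,
    cycles: int = 5,
    seed: int = 0,
    flank: int = 0,
    mask: MaskSet | None = None,
    **search_kwargs,
) -> list[SearchResult]:
    """Discover motifs recursively: find the lowest-entropy motif, mask every
    site it detects (Ri > ``site_threshold``), and rerun to surface the next
    one.

    ``classifier``, if given, is called on each round's :class:`SearchResult`
    and must return True (motif) or False (noise); discovery stops after the
    first noise round, which is returned flagged.  Masks accumulate across
    rounds so no round-k site overlaps an earlier round's mask.
    """
    from .scanning import ScanConfig, scan_sequence

    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    current = MaskSet()
    if mask is not None:
        current.update(mask)
    results: list[SearchResult] = []
    ss = np.random.SeedSequence(seed)
    round_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(max_rounds)]
    cfg = ScanConfig(threshold=site_threshold, overlap="best-per-window")
    for k in range(max_rounds):
        res = minimize_entropy(
            seqs, pattern, cycles=cycles, mask=current, seed=round_seeds[k],
            **search_kwargs,
        )
        res.round = k + 1
        if classifier is not None:
            res.accepted = bool(classifier(res))
        results.append(res)
        if res.accepted is False:
            break
        # record this round's sites (outside earlier masks) as new masks
        for i, s in enumerate(seqs):
            for site in scan_sequence(res.model, s, cfg, seq_id=str(i)):
                if site.ri > site_threshold and not current.overlaps(
                    i, site.start, site.end
                ):
                    current.add(i, max(0, site.start - flank), site.end + flank)
    return results
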