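"""Reading and writing peak sets, genomes, iPWM matrix files and site reports.

Coordinates are 0-based half-open everywhere (the native BED/narrowPeak
convention), including in site reports.  Peak datasets are kept sorted by
descending signal with deterministic tie-breaking so peak ranks — and hence
every rank-prefix derived from them — are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from pyfaidx import Fasta

from .information import (
    BindingSite,
    BipartiteModel,
    InformationWeightMatrix,
)

logger = logging.getLogger(__name__)

IPWM_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# peaks


@dataclass
class Peak:
    """A ChIP-seq peak interval with its signal strength (read-count scale)."""

    chrom: str
    start: int
    end: int
    signal: float
    rank: int | None = None
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.signal < 0:
            raise ValueError("negative signal")


@dataclass
class PeakDataset:
    """Peaks sorted by descending signal; rank 1 is the strongest peak."""

    peaks: list[Peak]
    source: str = ""

    @classmethod
    def from_peaks(cls, peaks: list[Peak], source: str = "") -> "PeakDataset":
        ordered = sorted(peaks, key=lambda p: (-p.signal, p.chrom, p.start))
        ordered = [replace(p, rank=i + 1) for i, p in enumerate(ordered)]
        return cls(ordered, source)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def top(self, k: int) -> "PeakDataset":
        """Rank prefix: the k strongest peaks (order and ranks preserved)."""
        return PeakDataset(self.peaks[:k], source=f"{self.source}[top {k}]")

    def signals(self) -> np.ndarray:
        return np.array([p.signal for p in self.peaks])

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peaks]


def read_peaks(
    path, format: str = "narrowPeak", signal_col: int = 4
) -> PeakDataset:
    """Read peaks from a narrowPeak or BED+signal file, rank-sorted.

    narrowPeak carries the signal in column 7 (``signalValue``); for plain
    BED dialects ``signal_col`` selects the 0-based signal column (default 4,
    the BED score).  Ties in signal are broken by (chrom, start) so ranks
    are deterministic.
    """
    if format not in ("narrowPeak", "bed"):
        raise ValueError(f"unknown peak format {format!r}")
    col = 6 if format == "narrowPeak" else signal_col
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) <= col:
                raise ValueError(
                    f"{path}: line {lineno}: missing signal column {col + 1}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                signal = float(fields[col])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed line ({exc})")
            peaks.append(Peak(chrom, start, end, signal))
    return PeakDataset.from_peaks(peaks, source=str(path))


def extract_sequences(
    ds: PeakDataset, genome_path, max_n_fraction: float = 0.5
) -> PeakDataset:
    """Attach uppercased genomic sequence to every peak (0-based half-open).

    Peaks whose sequence is more than ``max_n_fraction`` N are dropped (the
    count is logged).  Missing contigs or intervals beyond the contig end
    raise ``ValueError``.
    """
    genome = Fasta(str(genome_path), as_raw=True, sequence_always_upper=True)
    kept: list[Peak] = []
    dropped = 0
    for p in ds.peaks:
        if p.chrom not in genome:
            raise ValueError(f"contig {p.chrom!r} absent from genome")
        contig = genome[p.chrom]
        if p.end > len(contig):
            raise ValueError(
                f"interval {p.chrom}:{p.start}-{p.end} beyond contig end "
                f"({len(contig)})"
            )
        seq = contig[p.start : p.end]
        if seq.count("N") > max_n_fraction * len(seq):
            dropped += 1
            continue
        kept.append(replace(p, sequence=seq))
    if dropped:
        logger.info("dropped %d peaks with >%.0f%% N", dropped, 100 * max_n_fraction)
    out = PeakDataset.from_peaks(kept, source=ds.source)
    out.n_dropped = dropped
    return out


def read_peak_fasta(path) -> PeakDataset:
    """Read pre-extracted peak sequences from FASTA.

    Signals are taken from a ``signal=<float>`` token in the header; headers
    without one get signal 0.  Coordinates are synthesized as 0..len on a
    per-record pseudo-contig named by the FASTA id.
    """
    peaks: list[Peak] = []
    name, sig, chunks = None, 0.0, []

    def flush():
        if name is None:
            return
        seq = "".join(chunks).upper()
        if seq:
            peaks.append(Peak(name, 0, len(seq), sig, sequence=seq))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                flush()
                tokens = line[1:].split()
                name = tokens[0] if tokens else "unnamed"
                sig = 0.0
                for t in tokens[1:]:
                    if t.startswith("signal="):
                        sig = float(t[len("signal="):])
                chunks = []
            elif line:
                chunks.append(line)
    flush()
    return PeakDataset.from_peaks(peaks, source=str(path))


def write_peak_fasta(ds: PeakDataset, path) -> None:
    with open(path, "w") as fh:
        for p in ds.peaks:
            fh.write(f">{p.chrom} signal={p.signal:.6g}\n{p.sequence}\n")


def write_peaks_bed(ds: PeakDataset, path) -> None:
    """BED6 with the signal in the score column."""
    with open(path, "w") as fh:
        for p in ds.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak{p.rank}\t{p.signal:.6g}\t.\n")


# ---------------------------------------------------------------------------
# iPWM matrix files


def _write_matrix_block(fh, m: InformationWeightMatrix, label: str) -> None:
    fh.write(f"block\t{label}\n")
    fh.write(f"n\t{m.n}\n")
    fh.write(f"e_n\t{m.e_n:.6f}\n")
    fh.write(f"rsequence\t{m.rsequence:.6f}\n")
    fh.write(f"length\t{m.length}\n")
    fh.write("pos\tfA\tfC\tfG\tfT\twA\twC\twG\twT\n")
    for l in range(m.length):
        f = "\t".join(f"{m.freqs[b, l]:.6f}" for b in range(4))
        w = "\t".join(f"{m.weights[b, l]:.6f}" for b in range(4))
        fh.write(f"{l}\t{f}\t{w}\n")


def _read_matrix_block(lines: list[str], idx: int):
    def kv(expect):
        key, val = lines[idx[0]].split("\t", 1)
        if key != expect:
            raise ValueError(f"iPWM file: expected {expect!r}, found {key!r}")
        idx[0] += 1
        return val

    kv("block")
    n = int(kv("n"))
    e_n = float(kv("e_n"))
    rsequence = float(kv("rsequence"))
    length = int(kv("length"))
    idx[0] += 1  # column header
    freqs = np.zeros((4, length))
    weights = np.zeros((4, length))
    for l in range(length):
        fields = lines[idx[0]].split("\t")
        idx[0] += 1
        vals = [float(x) for x in fields[1:9]]
        if any(v < 0 for v in vals[:4]):
            raise ValueError("negative frequency in iPWM file")
        freqs[:, l] = vals[:4]
        weights[:, l] = vals[4:]
    from .information import position_entropies

    return InformationWeightMatrix(
        weights=weights,
        freqs=freqs,
        n=n,
        e_n=e_n,
        rsequence=rsequence,
        entropies=position_entropies(freqs),
    )


def write_ipwm(model, path) -> None:
    """Serialize a contiguous or bipartite iPWM to the versioned text format."""
    for arr in ([model.weights] if isinstance(model, InformationWeightMatrix)
                else [model.left.weights, model.right.weights]):
        if not np.all(np.isfinite(arr)):
            raise ValueError("model has non-finite weights")
    with open(path, "w") as fh:
        fh.write(f"#ipwm\tv{IPWM_FORMAT_VERSION}\n")
        if isinstance(model, InformationWeightMatrix):
            fh.write("kind\tcontiguous\n")
            _write_matrix_block(fh, model, "site")
        else:
            fh.write("kind\tbipartite\n")
            fh.write(f"pattern\t{model.pattern}\n")
            hist = "\t".join(str(int(c)) for c in model.gap_hist)
            fh.write(f"gap_hist\t{hist}\n")
            fh.write(f"gap_information\t{int(model.include_gap_information)}\n")
            _write_matrix_block(fh, model.left, "left")
            _write_matrix_block(fh, model.right, "right")


def read_ipwm(path):
    """Read an iPWM file written by :func:`write_ipwm`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("#ipwm\tv"):
        raise ValueError(f"{path}: not an iPWM file (missing version header)")
    version = int(lines[0].split("v", 1)[1])
    if version != IPWM_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported iPWM format version {version}")
    kind = lines[1].split("\t", 1)[1]
    idx = [2]
    if kind == "contiguous":
        return _read_matrix_block(lines, idx)
    if kind != "bipartite":
        raise ValueError(f"{path}: unknown model kind {kind!r}")
    from .patterns import parse_pattern

    pattern = parse_pattern(lines[2].split("\t", 1)[1])
    gap_hist = np.array([int(x) for x in lines[3].split("\t")[1:]], dtype=float)
    gap_info = bool(int(lines[4].split("\t", 1)[1]))
    idx = [5]
    left = _read_matrix_block(lines, idx)
    right = _read_matrix_block(lines, idx)
    return BipartiteModel(
        left=left, right=right, pattern=pattern, gap_hist=gap_hist,
        include_gap_information=gap_info,
    )


# ---------------------------------------------------------------------------
# site reports


SITE_REPORT_COLUMNS = ["chrom", "start", "end", "strand", "Ri_bits", "gap_nt", "sequence"]


def write_site_report(sites: list[BindingSite], path) -> None:
    """TSV site report, deterministically ordered by (chrom, start, strand)."""
    ordered = sorted(sites, key=lambda s: (s.seq_id, s.start, s.strand))
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_REPORT_COLUMNS) + "\n")
        for s in ordered:
            gap = "" if s.gap is None else str(s.gap)
            fh.write(
                f"{s.seq_id}\t{s.start}\t{s.end}\t{s.strand}\t{s.ri:.2f}\t{gap}\t{s.sequence}\n"
            )


def read_site_report(path) -> list[BindingSite]:
    sites: list[BindingSite] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SITE_REPORT_COLUMNS:
            raise ValueError(f"{path}: unexpected site report header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites.append(
                BindingSite(
                    seq_id=f[0], start=int(f[1]), end=int(f[2]), strand=f[3],
                    ri=float(f[4]), gap=int(f[5]) if f[5] else None, sequence=f[6],
                )
            )
    return sites
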