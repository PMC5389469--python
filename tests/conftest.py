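import numpy as np
import pytest

import ipwmkit as k


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_alignment(rng, n_seqs=40, seq_len=60, pattern=None):
    """A syntactically valid random alignment (offsets/strands/gaps drawn
    uniformly over legal placements) for identity and invariance tests."""
    pattern = pattern or k.contiguous(8)
    seqs, offsets, strands, gaps = [], [], [], []
    for _ in range(n_seqs):
        seq = "".join(rng.choice(list("ACGT"), size=seq_len))
        gap = (
            int(rng.integers(pattern.gap_min, pattern.gap_max + 1))
            if pattern.kind == "bipartite"
            else 0
        )
        span = pattern.span(gap) if pattern.kind == "bipartite" else pattern.left
        seqs.append(seq)
        offsets.append(int(rng.integers(0, seq_len - span + 1)))
        strands.append("+" if rng.random() < 0.5 else "-")
        gaps.append(gap)
    return k.AlignedSites(
        seqs, pattern, offsets=offsets, strands=strands,
        gaps=gaps if pattern.kind == "bipartite" else None,
    )


@pytest.fixture
def small_genome(tmp_path):
    path = tmp_path / "genome.fa"
    path.write_text(">chr1\nacgtACGTacgtACGT\n>chr2\nGGGGCCCCNNNNNNNNNNTT\n")
    return path
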