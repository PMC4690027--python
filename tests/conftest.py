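import numpy as np
import pandas as pd
import pytest

from stagetx.formats import BLAST_COLUMNS, BlastHitTable, StageCountMatrix
from stagetx.synthetic import GeneratorConfig, generate_bundle

STAGES = ["pre-competent larva", "post-larva", "adult"]


def make_matrix(rows: dict[str, tuple[int, int, int]]) -> StageCountMatrix:
    """Tiny count matrix from {contig: (pre, post, adult)}."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=STAGES, dtype=np.int64)
    df.index.name = "contig_id"
    return StageCountMatrix(df)


def make_hits(records: list[tuple]) -> BlastHitTable:
    """BlastHitTable from (qseqid, sseqid, sstart, send, qlen, slen) tuples."""
    rows = []
    for qid, sid, sstart, send, qlen, slen in records:
        rows.append({
            "qseqid": qid, "sseqid": sid, "pident": 90.0,
            "length": send - sstart + 1, "mismatch": 0, "gapopen": 0,
            "qstart": 1, "qend": send - sstart + 1, "sstart": sstart, "send": send,
            "evalue": 1e-20, "bitscore": 100.0, "qlen": qlen, "slen": slen,
        })
    df = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    df["reverse"] = False
    return BlastHitTable(df)


@pytest.fixture(scope="session")
def small_bundle():
    """A 600-gene synthetic bundle shared by integration-style tests."""
    cfg = GeneratorConfig(n_genes=600)
    return cfg, *generate_bundle(cfg, seed=7)
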