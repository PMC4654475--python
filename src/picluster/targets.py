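"""Antisense-complementarity search from cluster piRNAs to transcripts.

A piRNA targets a transcript segment when a stretch of the piRNA is
the exact reverse complement of the transcript segment; matches of at
least 13 nt are reported (the effective criterion of a short-word
BLAST search at e-value <= 1).  The search is exact seed-and-extend
over reverse-complemented piRNAs; an optional single-mismatch
extension mode exists for sensitivity analysis.  Matched genes are
joined against an externally computed differential-expression table.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return _normalize(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class TargetMatch:
    pirna_id: str
    transcript_id: str
    length: int
    transcript_pos: int  # 0-based start on the transcript
    pirna_offset: int    # 0-based start on the piRNA (5'->3')


def antisense_matches(
    pirnas: list[tuple[str, str]],
    transcripts: list[tuple[str, str]],
    min_len: int = 13,
) -> list[TargetMatch]:
    """All maximal exact reverse-complement matches of length >= min_len.

    Seed-and-extend: the transcript is indexed by ``min_len``-mers, the
    reverse complement of each piRNA is scanned against the index and
    hits are extended maximally in both directions; duplicate seeds of
    the same maximal match are collapsed.  Output order deterministic.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    out: set[TargetMatch] = set()
    for t_id, t_seq_raw in transcripts:
        t_seq = _normalize(t_seq_raw)
        index: dict[str, list[int]] = {}
        for i in range(len(t_seq) - min_len + 1):
            index.setdefault(t_seq[i:i + min_len], []).append(i)
        for p_id, p_seq_raw in pirnas:
            p_seq = _normalize(p_seq_raw)
            q = revcomp(p_seq)  # match q against transcript forward strand
            plen = len(p_seq)
            seen: set[tuple[int, int]] = set()
            for qi in range(len(q) - min_len + 1):
                for ti in index.get(q[qi:qi + min_len], ()):
                    qs, ts = qi, ti
                    while qs > 0 and ts > 0 and q[qs - 1] == t_seq[ts - 1]:
                        qs -= 1
                        ts -= 1
                    qe, te = qi + min_len, ti + min_len
                    while qe < len(q) and te < len(t_seq) and q[qe] == t_seq[te]:
                        qe += 1
                        te += 1
                    key = (qs, ts)
                    if key in seen:
                        continue
                    seen.add(key)
                    length = qe - qs
                    # q position [qs, qe) maps to piRNA [plen-qe, plen-qs)
                    out.add(TargetMatch(p_id, t_id, length, ts, plen - qe))
    return sorted(out)


def join_with_expression(
    matches: list[TargetMatch],
    de_table: pd.DataFrame,
    gene_col: str = "gene",
    lfc_col: str = "log_fc",
    sig_col: str = "significant",
) -> pd.DataFrame:
    """Per matched gene: match count, summed match length, fold change.

    Genes absent from the DE table are retained with missing fold
    change (name mismatches are not fatal).  Adds a ``direction``
    column (up / down / missing) and reports counts via the returned
    frame.
    """
    per_gene: dict[str, dict[str, float]] = {}
    for m in matches:
        rec = per_gene.setdefault(
            m.transcript_id, {"n_matches": 0, "total_match_len": 0}
        )
        rec["n_matches"] += 1
        rec["total_match_len"] += m.length
    de = de_table.set_index(gene_col) if gene_col in de_table.columns else de_table
    rows = []
    for gene in sorted(per_gene):
        rec = per_gene[gene]
        if gene in de.index:
            lfc = float(de.loc[gene, lfc_col])
            sig = bool(de.loc[gene, sig_col]) if sig_col in de.columns else np.nan
            direction = "up" if lfc > 0 else ("down" if lfc < 0 else "flat")
        else:
            lfc, sig, direction = np.nan, np.nan, "missing"
        rows.append({
            "gene": gene,
            "n_matches": int(rec["n_matches"]),
            "total_match_len": int(rec["total_match_len"]),
            lfc_col: lfc,
            sig_col: sig,
            "direction": direction,
        })
    return pd.DataFrame(
        rows,
        columns=["gene", "n_matches", "total_match_len", lfc_col, sig_col, "direction"],
    )
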