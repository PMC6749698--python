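"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a pipeline result by the most direct route possible
(plain loops, dicts and enumeration), sharing no code with the package, so
agreement is a genuine cross-check.
"""

from __future__ import annotations

import math
import statistics
from itertools import combinations


def hi3_pipeline_oracle(rows, n_replicates, min_peptides=3):
    """Straight-line reimplementation of the full Hi3 pipeline.

    ``rows`` are dicts with keys protein_id, peptide_seq, is_modified,
    strain_id, replicate_id, intensity.  Returns
    ``(hi3, fractions)`` keyed by (strain, replicate, protein); fractions
    cover quantifiable proteins only.
    """
    rows = [
        r
        for r in rows
        if not r["is_modified"]
        and r["intensity"] is not None
        and r["intensity"] > 0
    ]
    # per-sample medians
    by_sample = {}
    for r in rows:
        by_sample.setdefault((r["strain_id"], r["replicate_id"]), []).append(
            r["intensity"]
        )
    medians = {k: statistics.median(v) for k, v in by_sample.items()}
    # normalized intensities per (sample, protein)
    per_protein = {}
    for r in rows:
        key = (r["strain_id"], r["replicate_id"], r["protein_id"])
        per_protein.setdefault(key, []).append(
            r["intensity"] / medians[(r["strain_id"], r["replicate_id"])]
        )
    hi3 = {}
    for key, values in per_protein.items():
        if len(values) >= min_peptides:
            hi3[key] = sum(sorted(values)[-min_peptides:])
    # replicate filter per strain
    need = math.ceil(2 * n_replicates / 3)
    present = {}
    for (strain, rep, protein) in hi3:
        present.setdefault((strain, protein), set()).add(rep)
    quantifiable = {k for k, reps in present.items() if len(reps) >= need}
    # per-replicate fractions over quantifiable proteins
    totals = {}
    for (strain, rep, protein), value in hi3.items():
        if (strain, protein) in quantifiable:
            totals[(strain, rep)] = totals.get((strain, rep), 0.0) + value
    fractions = {
        (strain, rep, protein): value / totals[(strain, rep)]
        for (strain, rep, protein), value in hi3.items()
        if (strain, protein) in quantifiable
    }
    return hi3, fractions


def local_alignment_score_oracle(a, b, scores, gap_open, gap_extend):
    """Optimal local-alignment score by exhaustive skeleton enumeration.

    A local alignment is determined by its ordered set of aligned residue
    pairs; the gaps between consecutive pairs contribute affine penalties
    (first gap residue gap_open, each further gap_extend, per sequence).
    Enumerating every strictly increasing matching of positions of ``a``
    to positions of ``b`` therefore covers every local alignment; terminal
    unaligned residues are free.  ``scores`` maps residue pairs to
    substitution scores.
    """
    best = 0.0
    n, m = len(a), len(b)
    for k in range(1, min(n, m) + 1):
        for ia in combinations(range(n), k):
            for ib in combinations(range(m), k):
                score = 0.0
                for i, j in zip(ia, ib):
                    score += scores[a[i], b[j]]
                for t in range(k - 1):
                    di = ia[t + 1] - ia[t] - 1
                    dj = ib[t + 1] - ib[t] - 1
                    if di > 0:
                        score -= gap_open + (di - 1) * gap_extend
                    if dj > 0:
                        score -= gap_open + (dj - 1) * gap_extend
                if score > best:
                    best = score
    return best


_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def motif_scan_oracle(region, canonical, min_matches, both_strands=True):
    """Naive double-loop scan; returns sorted (start, strand, n_matches)."""
    region = region.upper()
    canonical = canonical.upper()
    k = len(canonical)
    hits = []
    for i in range(len(region) - k + 1):
        window = region[i : i + k]
        n = 0
        for x, y in zip(window, canonical):
            if x == y and x != "N":
                n += 1
        if n >= min_matches:
            hits.append((i, "+", n))
        if both_strands:
            rc = "".join(_RC[c] for c in reversed(window))
            n = 0
            for x, y in zip(rc, canonical):
                if x == y and x != "N":
                    n += 1
            if n >= min_matches:
                hits.append((i, "-", n))
    return sorted(hits)


def welch_t_oracle(x, y):
    """Textbook Welch t statistic, degrees of freedom and two-sided p."""
    import scipy.stats as st

    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * st.t.sf(abs(t), df)
    return t, df, p
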