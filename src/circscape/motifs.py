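"""PWM motif scanning with exact p-value thresholds and shuffle controls.

Motif matrices are position probability matrices over ACGT. Scoring is
log2 odds against a zero-order (single-nucleotide) background, with motif
probabilities floored at 1e-3 so zero entries stay finite. For each motif
the exact null score distribution is computed by dynamic programming over
positions with scores discretized to 1e-3 granularity; the match cutoff is
the smallest attainable score whose null tail probability is below the
requested p-value. Short motifs can be unmatchable at strict cutoffs: a
6-mer's best attainable tail under a uniform background is 4^-6 ~ 2.44e-4,
which is above the default 1e-4, so such a motif never matches; the cutoff
is configurable for users who want to trade stringency for sensitivity.

Control sequences are produced by the Altschul-Erikson dinucleotide-
preserving shuffle (uniform over Eulerian arrangements of the dinucleotide
multigraph).
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_2x2

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
PROB_FLOOR = 1e-3
SCORE_GRANULARITY = 1e-3
MIN_MOTIF_LEN = 6


@dataclass
class MotifPWM:
    motif_id: str
    rbp_names: list[str]
    matrix: np.ndarray  # L x 4, rows sum to 1
    consensus: str
    orientation: str = "given"

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "MotifPWM":
        rc = self.matrix[::-1, ::-1].copy()
        comp = str.maketrans(ALPHABET, "TGCA")
        return MotifPWM(
            self.motif_id,
            self.rbp_names,
            rc,
            self.consensus.translate(comp)[::-1],
            orientation="reverse_complement"
            if self.orientation == "given"
            else "given",
        )


def load_motif_db(db_path, pwm_path) -> list[MotifPWM]:
    """Load and clean an ATtRACT-style motif collection.

    `db_path` is a TSV with (at least) Matrix_id, Gene_name and Motif
    columns; `pwm_path` holds matrices as ">Matrix_id" headers followed by
    one "A C G T" probability row per position. Cleaning drops entries whose
    matrix length differs from the consensus length and motifs shorter than
    6 positions, normalizes rows off by more than 1e-6 (with a warning),
    rejects non-finite matrices, and merges entries with identical matrices
    into one record with concatenated, sorted names.
    """
    meta = pd.read_csv(db_path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in meta.columns}
    for need in ("matrix_id", "gene_name", "motif"):
        if need not in cols:
            raise ValueError(f"motif table missing column {need!r}")
    matrices: dict[str, list[list[float]]] = {}
    current = None
    with open(pwm_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split("\t")[0].split()[0]
                matrices[current] = []
            elif current is not None:
                matrices[current].append([float(x) for x in line.split()])

    raw: list[MotifPWM] = []
    for _, row in meta.iterrows():
        mid = row[cols["matrix_id"]]
        name = row[cols["gene_name"]]
        consensus = str(row[cols["motif"]]).upper()
        if mid not in matrices:
            continue
        mat = np.asarray(matrices[mid], dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4:
            continue
        if not np.isfinite(mat).all():
            print(f"warning: motif {mid} has non-finite entries; rejected", file=sys.stderr)
            continue
        if mat.shape[0] != len(consensus):
            continue  # spurious: PWM length differs from consensus length
        sums = mat.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            print(f"warning: motif {mid} rows renormalized", file=sys.stderr)
            mat = mat / sums[:, None]
        if mat.shape[0] < MIN_MOTIF_LEN:
            continue
        raw.append(MotifPWM(mid, [str(name)], mat, consensus))

    # merge identical matrices
    merged: dict[bytes, MotifPWM] = {}
    for m in raw:
        key = np.round(m.matrix, 9).tobytes()
        if key in merged:
            other = merged[key]
            other.rbp_names = sorted(set(other.rbp_names) | set(m.rbp_names))
            other.motif_id = ";".join(sorted(set(other.motif_id.split(";")) | {m.motif_id}))
        else:
            merged[key] = MotifPWM(m.motif_id, sorted(m.rbp_names), m.matrix, m.consensus)
    return sorted(merged.values(), key=lambda m: m.motif_id)


def background_from_sequences(sequences) -> np.ndarray:
    """Zero-order background: single-nucleotide frequencies over sequences."""
    counts = np.zeros(4)
    for seq in sequences:
        for b in seq.upper():
            i = _BASE_INDEX.get(b)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        raise ValueError("no ACGT symbols in background sequences")
    counts = np.where(counts == 0, 1.0, counts)  # keep strictly positive
    return counts / counts.sum()


def _int_score_matrix(pwm: MotifPWM, background: np.ndarray) -> np.ndarray:
    """Per-position integer log-odds scores at SCORE_GRANULARITY."""
    p = np.maximum(pwm.matrix, PROB_FLOOR)
    scores = np.log2(p / np.asarray(background))
    return np.round(scores / SCORE_GRANULARITY).astype(np.int64)


def exact_score_tail(
    int_scores: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the summed integer score.

    Returns (unique sums descending, P(score >= sum)) computed by dynamic
    programming over positions under the background model.
    """
    dist: dict[int, float] = {0: 1.0}
    bg = np.asarray(background, dtype=float)
    for row in int_scores:
        nxt: dict[int, float] = {}
        for total, prob in dist.items():
            for b in range(4):
                key = total + int(row[b])
                nxt[key] = nxt.get(key, 0.0) + prob * bg[b]
        dist = nxt
    sums = np.array(sorted(dist, reverse=True), dtype=np.int64)
    probs = np.array([dist[int(s)] for s in sums])
    return sums, np.cumsum(probs)


def score_threshold(
    pwm: MotifPWM, background, pvalue: float = 1e-4
) -> float:
    """Smallest score whose null tail probability is below `pvalue`.

    Returns +inf when no attainable score qualifies (the motif can then
    never match at this stringency).
    """
    bg = np.asarray(background, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background frequencies must be strictly positive")
    int_scores = _int_score_matrix(pwm, bg)
    sums, tails = exact_score_tail(int_scores, bg)
    qualifying = sums[tails < pvalue]
    if qualifying.size == 0:
        return math.inf
    return float(qualifying[-1]) * SCORE_GRANULARITY


def _scan_one(
    seq: str, int_scores: np.ndarray, cutoff_int: int
) -> tuple[int, int]:
    """(hits, skipped windows) for one oriented motif on one sequence."""
    L = int_scores.shape[0]
    n = len(seq)
    hits = skipped = 0
    idx = [_BASE_INDEX.get(c) for c in seq.upper()]
    for start in range(n - L + 1):
        window = idx[start : start + L]
        if any(i is None for i in window):
            skipped += 1
            continue
        score = sum(int(int_scores[k, i]) for k, i in enumerate(window))
        if score >= cutoff_int:
            hits += 1
    return hits, skipped


def scan_sequences(
    sequences: dict[str, str],
    motifs: list[MotifPWM],
    background,
    pvalue: float = 1e-4,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Count motif hits per sequence at exact p-value thresholds.

    Both orientations of every motif are scanned (each with its own exact
    cutoff under the shared background); overlapping hits count
    individually. Returns (sequences x motifs hit-count table, per-sequence
    tally of windows skipped for non-ACGT symbols).
    """
    bg = np.asarray(background, dtype=float)
    oriented = []
    for m in motifs:
        for om in (m, m.reverse_complement()):
            ints = _int_score_matrix(om, bg)
            sums, tails = exact_score_tail(ints, bg)
            qual = sums[tails < pvalue]
            cutoff = None if qual.size == 0 else int(qual[-1])
            oriented.append((m.motif_id, ints, cutoff))

    counts = pd.DataFrame(
        0, index=list(sequences), columns=[m.motif_id for m in motifs], dtype=int
    )
    skipped: dict[str, int] = {name: 0 for name in sequences}
    for name, seq in sequences.items():
        for motif_id, ints, cutoff in oriented:
            if cutoff is None:
                continue
            h, sk = _scan_one(seq, ints, cutoff)
            counts.loc[name, motif_id] += h
            skipped[name] += sk
    return counts, skipped


def dinucleotide_shuffle(sequence: str, seed) -> str:
    """Altschul-Erikson shuffle preserving the dinucleotide multiset.

    The output starts and ends with the input's first and last nucleotide
    and is drawn uniformly from the Eulerian arrangements of the input's
    dinucleotide multigraph. `seed` may be an int or a numpy Generator.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    if any(c not in _BASE_INDEX for c in seq):
        raise ValueError("sequence contains non-ACGT symbols")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = sorted(edges)
    if len(set(seq)) == 1:  # single-letter sequence has one arrangement
        return seq

    # sample last edges until they form an arborescence into `last`
    for _ in range(10000):
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][int(rng.integers(0, len(edges[v])))]
        ok = True
        for v in vertices:
            if v == last:
                continue
            cur, steps = v, 0
            while cur != last and steps <= len(vertices):
                if cur not in last_edge:
                    ok = False
                    break
                cur = last_edge[cur]
                steps += 1
            if not ok or cur != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - bounded rejection sampling
        raise RuntimeError("failed to sample a valid shuffle")

    ordered: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v != last:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v != last:
            pool.append(last_edge[v])
        ordered[v] = pool

    out = [first]
    ptr = {v: 0 for v in vertices}
    cur = first
    total_edges = len(seq) - 1
    for _ in range(total_edges):
        nxt = ordered[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def motif_enrichment(
    targets: dict[str, str],
    controls: dict[str, str],
    motifs: list[MotifPWM],
    background,
    pvalue: float = 1e-4,
) -> pd.DataFrame:
    """Sequence-level motif enrichment of targets over controls.

    Per motif, a 2x2 table of sequences with >= 1 hit vs none (targets vs
    controls) is tested with a one-sided Fisher exact test (targets
    enriched) and BH-adjusted across motifs.
    """
    if not targets or not controls:
        raise ValueError("target and control sets must be non-empty")
    if not motifs:
        return pd.DataFrame(
            columns=[
                "motif_id", "rbp_names", "target_with_hit", "target_total",
                "control_with_hit", "control_total", "odds_ratio", "p_value", "q_value",
            ]
        )
    t_counts, _ = scan_sequences(targets, motifs, background, pvalue)
    c_counts, _ = scan_sequences(controls, motifs, background, pvalue)
    rows = []
    for m in motifs:
        t_hit = int((t_counts[m.motif_id] > 0).sum())
        c_hit = int((c_counts[m.motif_id] > 0).sum())
        table = [
            [t_hit, len(targets) - t_hit],
            [c_hit, len(controls) - c_hit],
        ]
        odds, p = fisher_2x2(table, alternative="greater")
        rows.append(
            {
                "motif_id": m.motif_id,
                "rbp_names": ";".join(m.rbp_names),
                "target_with_hit": t_hit,
                "target_total": len(targets),
                "control_with_hit": c_hit,
                "control_total": len(controls),
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
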