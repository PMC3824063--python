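"""RNA secondary-structure prediction and pre-miRNA structure filters.

Candidate precursor windows must fold into the canonical pre-miRNA
shape — a single stem-loop with an extensively paired stem — before
they are worth characterizing. This module provides:

* an internal minimum-free-energy folder: a Zuker-style dynamic
  program over a simplified nearest-neighbor energy model
  (stacked-pair energies derived from pair strengths, size-dependent
  hairpin and interior/bulge penalties, affine multiloop costs,
  minimum hairpin loop of 3, lonely pairs allowed). The model is
  deliberately small enough that exhaustive structure enumeration can
  verify the DP exactly on short sequences;
* an adapter for RNAfold (ViennaRNA) as an external thermodynamic
  backend, for parity with published MFE scales on real data;
* the four discard rules applied to folded precursors (single stem;
  >= 19 pairs in the precursor; >= 11 paired positions under the read
  cluster; known-miRNA overlap for the positive training set — the
  last one lives with the cluster labeling code).

Energies are kcal/mol; more negative = more stable. The MFE of a
sequence that cannot pair is 0.0 (the open chain).
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Energy model (simplified nearest-neighbor)
# ---------------------------------------------------------------------------

INF = 1e9
MIN_HAIRPIN = 3  # minimum unpaired bases in a hairpin loop
MAX_INTERIOR = 30  # cap on total unpaired bases in an interior/bulge loop

# base codes: A=0 C=1 G=2 U/T=3
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair "strength" used to build the stacking table: one stacked pair
# contributes -(strength(outer) + strength(inner)) kcal/mol
_PAIR_STRENGTH = np.full((4, 4), -1.0)
for _a, _b, _s in [(0, 3, 1.1), (3, 0, 1.1), (1, 2, 1.7), (2, 1, 1.7), (2, 3, 0.6), (3, 2, 0.6)]:
    _PAIR_STRENGTH[_a, _b] = _s

ML_INIT = 3.4  # multiloop closing penalty
ML_BRANCH = 0.4  # per branch (including the closing pair)
ML_UNPAIRED = 0.1  # per unpaired base inside a multiloop


@njit(cache=False)
def _hairpin_energy(size: int) -> float:
    return 5.0 + 0.25 * (size - MIN_HAIRPIN)


@njit(cache=False)
def _interior_energy(size: int) -> float:
    # bulge (one-sided) and internal loops share a size-only penalty
    return 3.0 + 0.3 * size


@njit(cache=False)
def _fill(seq: np.ndarray, strength: np.ndarray):
    """Fill V (closed), WM (multiloop segment) and W (exterior) tables."""
    n = seq.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    W = np.zeros(n + 1)  # W[j] = MFE of prefix seq[0:j]
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            si, sj = seq[i], seq[j]
            if strength[si, sj] > 0.0:
                best = _hairpin_energy(j - i - 1)
                # stack / bulge / interior closed by (k, l)
                kmax = min(i + 1 + MAX_INTERIOR, j - 2)
                for k in range(i + 1, kmax + 1):
                    size1 = k - i - 1
                    lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAX_INTERIOR - size1))
                    for l in range(lmin, j):
                        if V[k, l] >= INF:
                            continue
                        size = size1 + (j - l - 1)
                        if size == 0:
                            e = V[k, l] - (strength[si, sj] + strength[seq[k], seq[l]])
                        else:
                            e = V[k, l] + _interior_energy(size)
                        if e < best:
                            best = e
                # multiloop: >= 2 branches inside
                for m in range(i + 1, j - 1):
                    if WM[i + 1, m] < INF and WM[m + 1, j - 1] < INF:
                        e = ML_INIT + ML_BRANCH + WM[i + 1, m] + WM[m + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM: segment of a multiloop containing >= 1 branch
            best = INF
            if WM[i + 1, j] < INF:
                best = WM[i + 1, j] + ML_UNPAIRED
            if WM[i, j - 1] < INF and WM[i, j - 1] + ML_UNPAIRED < best:
                best = WM[i, j - 1] + ML_UNPAIRED
            if V[i, j] < INF and V[i, j] + ML_BRANCH < best:
                best = V[i, j] + ML_BRANCH
            for m in range(i, j):
                if WM[i, m] < INF and WM[m + 1, j] < INF:
                    e = WM[i, m] + WM[m + 1, j]
                    if e < best:
                        best = e
            WM[i, j] = best
    for j in range(1, n + 1):
        best = W[j - 1]
        for k in range(0, j):
            if V[k, j - 1] < INF:
                e = W[k] + V[k, j - 1]
                if e < best:
                    best = e
        W[j] = best
    return V, WM, W


# ---------------------------------------------------------------------------
# Structure container
# ---------------------------------------------------------------------------


@dataclass
class SecondaryStructure:
    """A folded structure: dot-bracket, pair table and MFE."""

    sequence: str
    dotbracket: str
    mfe: float
    pair_table: list[Optional[int]] = field(repr=False)

    @classmethod
    def from_dotbracket(cls, sequence: str, dotbracket: str, mfe: float) -> "SecondaryStructure":
        return cls(sequence, dotbracket, mfe, pair_table_from_dotbracket(dotbracket))

    @property
    def pairs(self) -> list[tuple[int, int]]:
        pt = self.pair_table
        return [(i, j) for i, j in enumerate(pt) if j is not None and j > i]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_hairpin_loops(self) -> int:
        return count_hairpin_loops(self)

    @property
    def overhangs(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Unpaired terminal intervals outside the outermost pair."""
        paired = [i for i, j in enumerate(self.pair_table) if j is not None]
        n = len(self.sequence)
        if not paired:
            return (0, n), (n, n)
        return (0, paired[0]), (paired[-1] + 1, n)

    @property
    def stem_arms(self) -> Optional[tuple[tuple[int, int], tuple[int, int]]]:
        """(5' arm, 3' arm) intervals for a single-stem structure, else None.

        The arms run from the outermost pair to the innermost pair of
        the (single) stem; loop-side boundaries are half-open.
        """
        if self.n_hairpin_loops != 1 or self.n_pairs == 0:
            return None
        prs = self.pairs
        i0 = min(p[0] for p in prs)
        j0 = max(p[1] for p in prs)
        i1 = max(p[0] for p in prs)
        j1 = min(p[1] for p in prs)
        return (i0, i1 + 1), (j1, j0 + 1)


def pair_table_from_dotbracket(db: str) -> list[Optional[int]]:
    pt: list[Optional[int]] = [None] * len(db)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pt


def count_hairpin_loops(s: SecondaryStructure) -> int:
    """Number of terminal loops: pairs with no pair nested inside."""
    pt = s.pair_table
    count = 0
    for i, j in s.pairs:
        if all(pt[k] is None for k in range(i + 1, j)):
            count += 1
    return count


# ---------------------------------------------------------------------------
# Scoring a given structure under the model (shared by DP and oracle)
# ---------------------------------------------------------------------------


def can_pair(a: str, b: str) -> bool:
    return _PAIR_STRENGTH[_CODE[a], _CODE[b]] > 0.0


def score_structure(sequence: str, pair_table: Sequence[Optional[int]]) -> float:
    """Free energy of one structure by loop decomposition.

    This is the definition of the internal energy model: hairpin,
    stack, interior/bulge and multiloop contributions summed over all
    closed pairs; the exterior loop is free. The MFE dynamic program
    must agree with the minimum of this function over all structures.
    """
    seq = sequence.upper().replace("U", "T")
    pt = pair_table
    energy = 0.0
    for i, j in [(i, j) for i, j in enumerate(pt) if j is not None and j > i]:
        if not can_pair(seq[i], seq[j]):
            raise ValueError(f"illegal pair {seq[i]}-{seq[j]} at ({i},{j})")
        # direct children of (i, j)
        children: list[tuple[int, int]] = []
        unpaired = 0
        k = i + 1
        while k < j:
            if pt[k] is not None:
                children.append((k, pt[k]))
                k = pt[k] + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            size = j - i - 1
            if size < MIN_HAIRPIN:
                raise ValueError("hairpin loop shorter than minimum")
            energy += float(_hairpin_energy(size))
        elif len(children) == 1:
            (k, l) = children[0]
            size = (k - i - 1) + (j - l - 1)
            if size == 0:
                energy -= float(
                    _PAIR_STRENGTH[_CODE[seq[i]], _CODE[seq[j]]]
                    + _PAIR_STRENGTH[_CODE[seq[k]], _CODE[seq[l]]]
                )
            else:
                energy += float(_interior_energy(size))
        else:
            energy += ML_INIT + ML_BRANCH * (len(children) + 1) + ML_UNPAIRED * unpaired
    return energy


# ---------------------------------------------------------------------------
# Folding (internal backend)
# ---------------------------------------------------------------------------

_EPS = 1e-6


def _traceback(seq: np.ndarray, V: np.ndarray, WM: np.ndarray, W: np.ndarray, strength: np.ndarray) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []

    def trace_v(i: int, j: int) -> None:
        pairs.append((i, j))
        target = V[i, j]
        if abs(_hairpin_energy(j - i - 1) - target) < _EPS:
            return
        kmax = min(i + 1 + MAX_INTERIOR, j - 2)
        for k in range(i + 1, kmax + 1):
            size1 = k - i - 1
            lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAX_INTERIOR - size1))
            for l in range(lmin, j):
                if V[k, l] >= INF:
                    continue
                size = size1 + (j - l - 1)
                if size == 0:
                    e = V[k, l] - (strength[seq[i], seq[j]] + strength[seq[k], seq[l]])
                else:
                    e = V[k, l] + _interior_energy(size)
                if abs(e - target) < _EPS:
                    trace_v(k, l)
                    return
        for m in range(i + 1, j - 1):
            if WM[i + 1, m] < INF and WM[m + 1, j - 1] < INF:
                e = ML_INIT + ML_BRANCH + WM[i + 1, m] + WM[m + 1, j - 1]
                if abs(e - target) < _EPS:
                    trace_wm(i + 1, m)
                    trace_wm(m + 1, j - 1)
                    return
        raise AssertionError("traceback failure in V")

    def trace_wm(i: int, j: int) -> None:
        target = WM[i, j]
        if V[i, j] < INF and abs(V[i, j] + ML_BRANCH - target) < _EPS:
            trace_v(i, j)
            return
        if i + 1 <= j and WM[i + 1, j] < INF and abs(WM[i + 1, j] + ML_UNPAIRED - target) < _EPS:
            trace_wm(i + 1, j)
            return
        if i <= j - 1 and WM[i, j - 1] < INF and abs(WM[i, j - 1] + ML_UNPAIRED - target) < _EPS:
            trace_wm(i, j - 1)
            return
        for m in range(i, j):
            if WM[i, m] < INF and WM[m + 1, j] < INF and abs(WM[i, m] + WM[m + 1, j] - target) < _EPS:
                trace_wm(i, m)
                trace_wm(m + 1, j)
                return
        raise AssertionError("traceback failure in WM")

    j = len(seq)
    while j > 0:
        if abs(W[j] - W[j - 1]) < _EPS:
            j -= 1
            continue
        for k in range(0, j):
            if V[k, j - 1] < INF and abs(W[k] + V[k, j - 1] - W[j]) < _EPS:
                trace_v(k, j - 1)
                j = k
                break
        else:
            raise AssertionError("traceback failure in W")
    return pairs


def fold(sequence: str, engine: str | Callable[[str], SecondaryStructure] = "internal") -> SecondaryStructure:
    """Fold one sequence to its MFE structure.

    ``engine`` selects the backend: "internal" (default), "vienna"
    (RNAfold subprocess), or any callable mapping a sequence to a
    :class:`SecondaryStructure`.
    """
    seq = sequence.upper().replace("U", "T")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    if callable(engine):
        return engine(sequence)
    if engine == "vienna":
        return fold_vienna(sequence)
    if engine != "internal":
        raise ValueError(f"unknown folding engine {engine!r}")

    enc = np.array([_CODE[c] for c in seq], dtype=np.int8)
    n = len(enc)
    if n <= MIN_HAIRPIN + 1:
        return SecondaryStructure(sequence, "." * n, 0.0, [None] * n)
    V, WM, W = _fill(enc, _PAIR_STRENGTH)
    mfe = float(W[n])
    pairs = _traceback(enc, V, WM, W, _PAIR_STRENGTH) if mfe < -_EPS else []
    pt: list[Optional[int]] = [None] * n
    db = ["."] * n
    for i, j in pairs:
        pt[i], pt[j] = j, i
        db[i], db[j] = "(", ")"
    return SecondaryStructure(sequence, "".join(db), round(mfe, 6), pt)


def fold_vienna(sequence: str) -> SecondaryStructure:
    """Fold via the RNAfold command-line tool (external backend)."""
    rna = sequence.upper().replace("T", "U")
    proc = subprocess.run(
        ["RNAfold", "--noPS"], input=rna + "\n", capture_output=True, text=True, check=True
    )
    lines = proc.stdout.strip().splitlines()
    struct_line = lines[-1]
    db = struct_line.split(None, 1)[0]
    mfe = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
    return SecondaryStructure.from_dotbracket(sequence, db, mfe)


# ---------------------------------------------------------------------------
# Structure filters
# ---------------------------------------------------------------------------


@dataclass
class StructureFilterConfig:
    """Thresholds for the precursor structure discard rules."""

    min_pairs_precursor: int = 19  # base pairs in the whole precursor
    min_pairs_cluster: int = 11  # paired positions under the read cluster
    require_single_stem: bool = True


def passes_structure_filters(
    cluster_offset: tuple[int, int],
    s: SecondaryStructure,
    cfg: StructureFilterConfig | None = None,
) -> tuple[bool, str]:
    """Apply the hairpin-shape discard rules to one folded precursor.

    ``cluster_offset`` is the read-cluster interval in window
    coordinates. Rules, in order: the structure must be a single-stem
    hairpin (exactly one terminal loop); it must contain at least
    ``min_pairs_precursor`` base pairs; at least ``min_pairs_cluster``
    nucleotide positions within the cluster must be paired. The
    cluster-level rule counts paired *positions*, not pairs: the
    cluster occupies one stem arm, so its partners lie outside it.

    Returns (passed, reason) where reason names the first failed rule.
    """
    cfg = cfg or StructureFilterConfig()
    if cfg.require_single_stem and s.n_hairpin_loops != 1:
        return False, "single_stem"
    if s.n_pairs < cfg.min_pairs_precursor:
        return False, "min_pairs_precursor"
    c0, c1 = cluster_offset
    paired_in_cluster = sum(1 for k in range(c0, c1) if s.pair_table[k] is not None)
    if paired_in_cluster < cfg.min_pairs_cluster:
        return False, "min_pairs_cluster"
    return True, ""


def write_vienna(records: Sequence[tuple[str, SecondaryStructure]], path) -> None:
    """Serialize structures as Vienna-style 3-line records."""
    with open(path, "w") as fh:
        for name, s in records:
            fh.write(f">{name}\n{s.sequence}\n{s.dotbracket} ({s.mfe:.2f})\n")
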