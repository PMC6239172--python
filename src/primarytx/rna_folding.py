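"""Minimum free energy folding of 5'-UTRs under a simplified pair-energy model.

The built-in engine minimizes a sum of base-pair stacking-free energies
(GC/CG -3.0, AU/UA -2.0, GU/UG -1.0 kcal/mol) over all nested
secondary structures with a minimum hairpin loop of 3 unpaired bases —
a Nussinov-style dynamic program with energies instead of pair counts.
This deliberately simplified model keeps an exhaustive enumeration
oracle feasible and preserves the ordering property that matters for
leader analysis (structured sequences score far below unstructured
ones); it does not attempt absolute free-energy parity with a full
nearest-neighbor thermodynamic folder. A full folder (e.g. an external
RNAfold binary) can be plugged in through the engine interface of
``utr_mfe_table``.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_PAIR_ENERGIES = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


@dataclass
class EnergyParams:
    """Pair energies (kcal/mol, all < 0) and the minimum hairpin loop size."""

    pair_energies: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_ENERGIES)
    )
    min_loop: int = 3
    temperature: str = "37C"  # metadata only; the model has no T dependence

    def __post_init__(self) -> None:
        if any(e >= 0 for e in self.pair_energies.values()):
            raise ValueError("all pair energies must be negative")
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")


@dataclass(frozen=True)
class FoldResult:
    sequence: str
    mfe: float              # kcal/mol, <= 0
    structure: str          # dot-bracket, same length as sequence


def _as_rna(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    if not seq:
        raise ValueError("empty sequence")
    return seq


def fold_mfe(sequence: str, params: EnergyParams | None = None) -> FoldResult:
    """MFE and one optimal structure by dynamic programming over nested pairings.

    E(i,j) = min( E(i+1,j),
                  min_k e(i,k) + E(i+1,k-1) + E(k+1,j) ),
    where k ranges over partners of i with at least min_loop unpaired
    bases between them. Traceback is deterministic: at each position the
    pairing with the smallest partner index achieving the optimum is
    preferred over leaving the base unpaired.
    """
    params = params or EnergyParams()
    seq = _as_rna(sequence)
    n = len(seq)
    pe, min_loop = params.pair_energies, params.min_loop
    E = [[0.0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = E[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                e = pe.get((seq[i], seq[k]))
                if e is None:
                    continue
                left = E[i + 1][k - 1] if k - 1 > i + 1 else 0.0
                right = E[k + 1][j] if k + 1 < j else 0.0
                cand = e + left + right
                if cand < best:
                    best = cand
            E[i][j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            e = pe.get((seq[i], seq[k]))
            if e is None:
                continue
            left = E[i + 1][k - 1] if k - 1 > i + 1 else 0.0
            right = E[k + 1][j] if k + 1 < j else 0.0
            # pairing energies are strictly negative, so a pairing branch can
            # only tie E(i,j) when it is genuinely optimal; prefer smallest k
            if e + left + right == E[i][j]:
                structure[i], structure[k] = "(", ")"
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    mfe = E[0][n - 1] if n > 1 else 0.0
    return FoldResult(seq, mfe, "".join(structure))


def score_structure(sequence: str, structure: str, params: EnergyParams | None = None) -> float:
    """Energy of a dot-bracket structure under the pair-energy model.

    Also validates the structure: balanced nesting, legal pairs and the
    minimum hairpin loop.
    """
    params = params or EnergyParams()
    seq = _as_rna(sequence)
    if len(structure) != len(seq):
        raise ValueError("structure/sequence length mismatch")
    stack: list[int] = []
    energy = 0.0
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            i = stack.pop()
            if (seq[i], seq[idx]) not in params.pair_energies:
                raise ValueError(f"illegal pair {seq[i]}-{seq[idx]} at ({i},{idx})")
            # the model requires every pair to span >= min_loop intervening bases
            if idx - i - 1 < params.min_loop:
                raise ValueError(f"pair span shorter than min loop at ({i},{idx})")
            energy += params.pair_energies[(seq[i], seq[idx])]
        elif ch != ".":
            raise ValueError(f"bad structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced structure")
    return energy


def brute_force_fold(sequence: str, params: EnergyParams | None = None,
                     max_len: int = 18) -> FoldResult:
    """Exhaustive-enumeration folding oracle (length-guarded).

    Enumerates every legal nested pairing and returns a minimum-energy
    one; intended as an independent check of fold_mfe on short inputs.
    """
    params = params or EnergyParams()
    seq = _as_rna(sequence)
    if len(seq) > max_len:
        raise ValueError(f"brute force limited to length <= {max_len}")
    pe, min_loop = params.pair_energies, params.min_loop

    def enumerate_structures(i: int, j: int):
        # yields (energy, structure) for subsequence [i, j]
        if i > j:
            yield 0.0, ""
            return
        for e_rest, s_rest in enumerate_structures(i + 1, j):
            yield e_rest, "." + s_rest
        for k in range(i + min_loop + 1, j + 1):
            e = pe.get((seq[i], seq[k]))
            if e is None:
                continue
            for e_in, s_in in enumerate_structures(i + 1, k - 1):
                for e_out, s_out in enumerate_structures(k + 1, j):
                    yield e + e_in + e_out, "(" + s_in + ")" + s_out

    best_e, best_s = 0.0, "." * len(seq)
    for e, s in enumerate_structures(0, len(seq) - 1):
        if e < best_e:
            best_e, best_s = e, s
    return FoldResult(seq, best_e, best_s)


def viennarna_engine(sequence: str, params: EnergyParams | None = None) -> FoldResult:
    """External plug-in engine calling an RNAfold binary, if available."""
    if shutil.which("RNAfold") is None:
        raise RuntimeError("RNAfold binary not found on PATH")
    seq = _as_rna(sequence)
    proc = subprocess.run(
        ["RNAfold", "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    )
    lines = proc.stdout.strip().splitlines()
    match = re.match(r"^([.()]+)\s+\(\s*(-?\d+(?:\.\d+)?)\s*\)", lines[-1])
    if match is None:
        raise RuntimeError(f"unparseable RNAfold output: {lines[-1]!r}")
    return FoldResult(seq, float(match.group(2)), match.group(1))


ENGINES = {
    "builtin": fold_mfe,
    "brute": brute_force_fold,
    "viennarna": viennarna_engine,
}


def utr_mfe_table(utrs, params: EnergyParams | None = None, engine="builtin") -> pd.DataFrame:
    """Fold each leader UTR; returns gene_id, length, mfe, structure, note.

    Leaderless entries get NaN energies with a note and are meant to be
    excluded from summaries. Per-record engine failures are recorded in
    the note column and the run continues.
    """
    params = params or EnergyParams()
    fold = ENGINES[engine] if isinstance(engine, str) else engine
    rows = []
    for u in utrs:
        row = {"gene_id": u.gene_id, "length": u.length, "mfe": float("nan"),
               "structure": "", "note": ""}
        if u.leader_status == "leaderless" or not u.sequence:
            row["note"] = "leaderless; excluded from folding"
        else:
            try:
                result = fold(u.sequence, params)
                row["mfe"], row["structure"] = result.mfe, result.structure
            except Exception as exc:  # engine failure surfaces per record
                row["note"] = f"engine failure: {exc}"
                log.warning("folding failed for %s: %s", u.gene_id, exc)
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene_id", "length", "mfe", "structure", "note"])
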