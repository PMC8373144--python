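"""Minimum-free-energy RNA secondary structure for guide RNAs.

Guide efficacy in the emulated experiment anti-correlates with the folding
stability of the crRNA: guides whose 20-21 nt recognition sequence folds
below about -4 kcal/mol are poor cutters, and purine-only guides (GAA
repeats) cannot form any Watson-Crick or GU pair and hence have no
structure at all.

The folder is a Zuker-style dynamic program over pseudoknot-free
structures — Watson-Crick and GU pairs, hairpin loops of at least three
unpaired bases, nearest-neighbor stack energies with ΔG(T) = ΔH - T·ΔS,
linear hairpin/internal/bulge loop penalties and an affine multiloop
penalty.  The parameter set is a reduced Turner-style table (recorded in
:data:`STACK_DG37`/:data:`STACK_DH`): it does not numerically reproduce any
particular external folding engine, and conclusions drawn from it are
rank-level.  An external engine can be substituted through the ``backend``
argument of :func:`fold_mfe`.

Energies are handled internally as integer hundredths of kcal/mol so that
co-optimal ties are exact; among co-optimal structures the lexicographically
smallest dot-bracket string is returned.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable, Sequence

import pandas as pd

PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})
MIN_HAIRPIN = 3  # unpaired bases in a hairpin loop
MAX_INTERIOR = 20  # max unpaired bases in an internal/bulge loop

# Reduced nearest-neighbor stack table, kcal/mol at 37 degC. Key "WX/YZ" is
# the stack of outer pair W-Z on inner pair X-Y, read 5'->3' on the top
# strand. Watson-Crick values follow the familiar ten-parameter table;
# stacks involving GU pairs use a flat reduced value.
STACK_DG37 = {
    "AA/UU": -0.93, "AU/AU": -1.10, "UA/UA": -1.33,
    "CU/AG": -2.08, "CA/UG": -2.11, "GU/AC": -2.24,
    "GA/UC": -2.35, "CG/CG": -2.36, "GG/CC": -3.26, "GC/GC": -3.42,
}
GU_STACK_DG37 = -1.20  # any stack with >= 1 GU pair
GU_GU_STACK_DG37 = -0.50  # both pairs GU

# Enthalpies approximated as a fixed multiple of dG37 (reduced model);
# dS = (dH - dG37)/310.15 then dG(T) = dH - (T+273.15) dS.
DH_RATIO = 3.4

# Loop penalties, kcal/mol, temperature-independent in this reduced model.
HAIRPIN_A, HAIRPIN_B = 4.50, 0.20  # a + b * loop_len
INTERIOR_A, INTERIOR_B = 3.50, 0.30
MULTI_A, MULTI_B, MULTI_C = 3.40, 0.40, 0.20  # closing + per-branch + per-unpaired

INF = 10 ** 9


@dataclass(frozen=True)
class FoldResult:
    """MFE fold of one sequence. ``delta_g`` is in kcal/mol and is ``None``
    when no negative-energy structure exists ("no structure")."""

    sequence: str
    temperature_celsius: float
    delta_g: float | None
    structure: str

    @property
    def no_structure(self) -> bool:
        return self.delta_g is None


def _normalize_rna(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("AUGC")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


@lru_cache(maxsize=8)
def _param_table(temperature: float) -> dict[str, int]:
    """Integer centikcal stack energies at the requested temperature."""
    T = temperature + 273.15
    out: dict[str, int] = {}
    bases = "AUGC"
    for w in bases:
        for x in bases:
            for y in bases:
                for z in bases:
                    outer, inner = w + z, x + y
                    if outer not in PAIRS or inner not in PAIRS:
                        continue
                    key = f"{w}{x}/{y}{z}"
                    # the same physical stack read from the other strand has
                    # the two halves swapped
                    dg37 = STACK_DG37.get(key, STACK_DG37.get(f"{y}{z}/{w}{x}"))
                    if dg37 is None:
                        n_gu = (outer in ("GU", "UG")) + (inner in ("GU", "UG"))
                        dg37 = GU_GU_STACK_DG37 if n_gu == 2 else GU_STACK_DG37
                    dh = DH_RATIO * dg37
                    ds = (dh - dg37) / 310.15
                    out[key] = round(100 * (dh - T * ds))
    return out


def _hairpin(loop_len: int) -> int:
    return round(100 * (HAIRPIN_A + HAIRPIN_B * loop_len))


def _interior(loop_len: int) -> int:
    return round(100 * (INTERIOR_A + INTERIOR_B * loop_len))


_M_A = round(100 * MULTI_A)
_M_B = round(100 * MULTI_B)
_M_C = round(100 * MULTI_C)


def _can_pair(a: str, b: str) -> bool:
    return a + b in PAIRS


def structure_energy(sequence: str, pairs: Iterable[tuple[int, int]],
                     temperature: float = 30.0) -> float:
    """Energy (kcal/mol) of an explicit pair set under the folder's model.

    The structure is decomposed into its loops (hairpin, stack,
    internal/bulge, multiloop) and scored with exactly the tables the DP
    uses, so this doubles as an independent scorer for enumeration checks.
    Invalid structures (crossing pairs, unpairable bases, hairpins < 3,
    oversized interior loops) raise ``ValueError``.
    """
    seq = _normalize_rna(sequence)
    e = _structure_energy_int(seq, tuple(sorted(pairs)), temperature)
    return e / 100.0


def _structure_energy_int(seq: str, pairs: tuple[tuple[int, int], ...],
                          temperature: float) -> int:
    stacks = _param_table(temperature)
    n = len(seq)
    partner = {}
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise ValueError(f"pair ({i},{j}) out of range")
        if i in partner or j in partner:
            raise ValueError("base paired twice")
        if not _can_pair(seq[i], seq[j]):
            raise ValueError(f"unpairable bases {seq[i]}{seq[j]} at ({i},{j})")
        partner[i] = j
        partner[j] = i
    for (i, j) in pairs:
        for (k, l) in pairs:
            if i < k < j < l:
                raise ValueError("crossing pairs (pseudoknot)")

    def children_of(i: int, j: int) -> list[tuple[int, int]]:
        kids = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return kids

    total = 0
    for (i, j) in pairs:
        kids = children_of(i, j)
        if not kids:
            loop = j - i - 1
            if loop < MIN_HAIRPIN:
                raise ValueError(f"hairpin loop of {loop} < {MIN_HAIRPIN}")
            total += _hairpin(loop)
        elif len(kids) == 1:
            (k, l) = kids[0]
            if k == i + 1 and l == j - 1:
                total += stacks[f"{seq[i]}{seq[k]}/{seq[l]}{seq[j]}"]
            else:
                loop = (k - i - 1) + (j - l - 1)
                if loop > MAX_INTERIOR:
                    raise ValueError(f"interior loop of {loop} > {MAX_INTERIOR}")
                total += _interior(loop)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            total += _M_A + _M_B * (1 + len(kids)) + _M_C * unpaired
    return total


# ---------------------------------------------------------------------------
# Zuker DP over (energy, dot-bracket) tuples
# ---------------------------------------------------------------------------

def _fold_dp(seq: str, temperature: float) -> tuple[int, str]:
    """MFE and lexicographically smallest co-optimal dot-bracket."""
    stacks = _param_table(temperature)
    n = len(seq)
    BIG = (INF, "")
    # V[i][j]: best closed structure with (i,j) paired; WM/WM1: multiloop
    # segment with >=1 branch / first branch anchored at the left end.
    V = [[BIG] * n for _ in range(n)]
    WM = [[BIG] * n for _ in range(n)]
    WM1 = [[BIG] * n for _ in range(n)]

    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            if _can_pair(seq[i], seq[j]):
                best = (_hairpin(j - i - 1), "(" + "." * (j - i - 1) + ")")
                # stack / interior / bulge
                for k in range(i + 1, j):
                    if j - 1 - k < MIN_HAIRPIN + 1:
                        break
                    left = k - i - 1
                    if left > MAX_INTERIOR:
                        break
                    for l in range(j - 1, k, -1):
                        right = j - l - 1
                        if left + right > MAX_INTERIOR:
                            break
                        ev, sv = V[k][l]
                        if ev >= INF:
                            continue
                        if left == 0 and right == 0:
                            e = ev + stacks[f"{seq[i]}{seq[k]}/{seq[l]}{seq[j]}"]
                        else:
                            e = ev + _interior(left + right)
                        cand = (e, "(" + "." * left + sv + "." * right + ")")
                        if cand < best:
                            best = cand
                # multiloop: >= 2 branches inside
                for k in range(i + 2, j - 1):
                    ew, sw = WM[i + 1][k - 1]
                    e1, s1 = WM1[k][j - 1]
                    if ew >= INF or e1 >= INF:
                        continue
                    cand = (ew + e1 + _M_A + _M_B, "(" + sw + s1 + ")")
                    if cand < best:
                        best = cand
                V[i][j] = best

            # WM1[i][j]: first branch starts exactly at i
            best1 = BIG
            for m in range(i + MIN_HAIRPIN + 1, j + 1):
                ev, sv = V[i][m]
                if ev >= INF:
                    continue
                cand = (ev + _M_B + _M_C * (j - m), sv + "." * (j - m))
                if cand < best1:
                    best1 = cand
            WM1[i][j] = best1

            # WM[i][j]
            bestm = best1
            em, sm = WM[i + 1][j] if i + 1 <= j else BIG
            if em < INF:
                cand = (em + _M_C, "." + sm)
                if cand < bestm:
                    bestm = cand
            for k in range(i + 1, j):
                ea, sa = WM[i][k - 1]
                eb, sb = WM1[k][j]
                if ea >= INF or eb >= INF:
                    continue
                cand = (ea + eb, sa + sb)
                if cand < bestm:
                    bestm = cand
            WM[i][j] = bestm

    # exterior loop
    W: list[tuple[int, str]] = [(0, "")] * (n + 1)
    for j in range(n):
        best = (W[j][0], W[j][1] + ".")
        for i in range(0, j):
            ev, sv = V[i][j]
            if ev >= INF:
                continue
            cand = (W[i][0] + ev, W[i][1] + sv)
            if cand < best:
                best = cand
        W[j + 1] = best
    return W[n]


FoldBackend = Callable[[str, float], tuple[float | None, str]]


def fold_mfe(sequence: str, temperature: float = 30.0,
             backend: FoldBackend | None = None) -> FoldResult:
    """Minimum-free-energy fold of one RNA sequence.

    ``temperature`` is in degrees Celsius (default 30, the growth
    temperature of the emulated experiment; 37 is also commonly used).
    DNA input (T) is auto-converted to RNA (U).  When no structure with
    negative energy exists — e.g. any purine-only sequence, which cannot
    form a single WC or GU pair — the result reports "no structure".

    A ``backend`` callable ``(sequence, temperature) -> (dg, structure)``
    substitutes an external folding engine for the built-in DP.
    """
    seq = _normalize_rna(sequence)
    if len(seq) == 0:
        raise ValueError("empty sequence")
    if backend is not None:
        dg, structure = backend(seq, temperature)
        if dg is None or dg >= 0:
            return FoldResult(seq, temperature, None, "." * len(seq))
        return FoldResult(seq, temperature, float(dg), structure)
    if len(seq) < MIN_HAIRPIN + 2:
        return FoldResult(seq, temperature, None, "." * len(seq))
    e, s = _fold_dp(seq, temperature)
    if e >= 0:
        return FoldResult(seq, temperature, None, "." * len(seq))
    return FoldResult(seq, temperature, e / 100.0, s)


def rnafold_cli_backend(sequence: str, temperature: float) -> tuple[float | None, str]:
    """Adapter running the ViennaRNA ``RNAfold`` executable, for users who
    want a full Turner-parameter engine behind the same interface."""
    proc = subprocess.run(
        ["RNAfold", "--noPS", "-T", str(temperature)],
        input=sequence + "\n", capture_output=True, text=True, check=True,
    )
    line = proc.stdout.strip().splitlines()[-1]
    structure, _, energy = line.partition(" ")
    dg = float(energy.strip().strip("()"))
    if structure.count("(") == 0:
        return None, "." * len(sequence)
    return dg, structure


def fold_guide_set(
    crRNAs: Sequence[tuple[str, str]],
    scaffold: str,
    temperature: float = 30.0,
    backend: FoldBackend | None = None,
) -> pd.DataFrame:
    """Fold each crRNA alone and fused to its scaffold (the full sgRNA).

    ``crRNAs`` is a list of (guide_id, sequence).  Returns a table with
    per-guide ΔG for the crRNA and the sgRNA plus the stability class of
    the crRNA.  The scaffold (tracrRNA-derived part) is a required input:
    it differs per nuclease and is supplied by the caller.
    """
    scaffold = _normalize_rna(scaffold) if scaffold else ""
    rows = []
    for gid, seq in crRNAs:
        cr = fold_mfe(seq, temperature, backend)
        sg = fold_mfe(_normalize_rna(seq) + scaffold, temperature, backend) if scaffold else cr
        rows.append(
            {
                "guide_id": gid,
                "length": len(cr.sequence),
                "dG_crRNA": cr.delta_g,
                "dG_sgRNA": sg.delta_g,
                "crRNA_structure": cr.structure,
                "stability_class": stability_class(cr.delta_g),
            }
        )
    return pd.DataFrame(rows)


def stability_class(delta_g: float | None, threshold: float = -4.0) -> str:
    """'stable' below the threshold (strict), 'unstructured' when no
    structure exists, 'unstable' otherwise.  The default -4 kcal/mol is the
    stability level below which structured crRNAs stop cutting efficiently."""
    if delta_g is None:
        return "unstructured"
    if delta_g < threshold:
        return "stable"
    return "unstable"
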