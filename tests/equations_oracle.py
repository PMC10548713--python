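"""Independent straight-from-the-definitions oracle used by the tests.

Every function here recomputes a feature or metric with plain Python loops
and ``math``, deliberately sharing no code path with the package
implementation (the bundled constant tables are shared, since they are data,
not computation).  Tests compare the vectorized implementation against these
naive versions.
"""

from __future__ import annotations

import math

from rmethyl import constants

AA = sorted("ACDEFGHIKLMNPQRSTVWY")


def aac(seq: str) -> list[float]:
    return [sum(1 for ch in seq if ch == a) / len(seq) for a in AA]


def dpc(seq: str) -> list[float]:
    out = []
    for a in AA:
        for b in AA:
            count = 0
            for i in range(len(seq) - 1):
                if seq[i] == a and seq[i + 1] == b:
                    count += 1
            out.append(count / len(seq))
    return out


def probabilities(seq: str) -> list[float]:
    return aac(seq)


def shannon(p: list[float]) -> float:
    return -sum(pi * math.log2(pi) for pi in p if pi > 0)


def relative_shannon(p: list[float], p0: float = 1 / 20) -> float:
    return sum(pi * math.log2(pi / p0) for pi in p if pi > 0)


def havrda_charvat(p: list[float], alpha: float) -> float:
    s = sum(pi ** alpha for pi in p if pi > 0)
    return (s - 1.0) / (2.0 ** (1.0 - alpha) - 1.0)


def renyi(p: list[float], alpha: float) -> float:
    s = sum(pi ** alpha for pi in p if pi > 0)
    return math.log2(s) / (1.0 - alpha)


def arimoto(p: list[float], alpha: float) -> float:
    s = sum(pi ** (1.0 / alpha) for pi in p if pi > 0)
    return (s ** alpha - 1.0) / (2.0 ** (alpha - 1.0) - 1.0)


def gravy(seq: str) -> float:
    kd = constants.hydropathy()
    residues = [ch for ch in seq if ch != "X"]
    return sum(kd[ch] for ch in residues) / len(residues)


def instability_index(seq: str) -> float:
    table = constants.diwv()
    length = sum(1 for ch in seq if ch != "X")
    total = 0.0
    for i in range(len(seq) - 1):
        if seq[i] != "X" and seq[i + 1] != "X":
            total += table[seq[i] + seq[i + 1]]
    return 10.0 / length * total


def extinction(seq: str, oxidized: bool) -> float:
    me = constants.extinction_coefficients()
    n_c = sum(1 for ch in seq if ch == "C")
    value = me["Trp"] * sum(1 for ch in seq if ch == "W")
    value += me["Tyr"] * sum(1 for ch in seq if ch == "Y")
    if oxidized:
        value += me["cystine"] * (n_c // 2)
    return value


def molecular_weight(seq: str) -> float:
    masses = constants.residue_masses()
    residues = [ch for ch in seq if ch != "X"]
    return sum(masses[ch] for ch in residues) - (len(residues) - 1) * constants.WATER_MASS


def aromaticity(seq: str) -> float:
    residues = [ch for ch in seq if ch != "X"]
    return sum(1 for ch in residues if ch in "FWY") / len(residues)


def ss_fractions(seq: str) -> tuple[float, float, float]:
    classes = constants.secondary_structure_classes()
    residues = [ch for ch in seq if ch != "X"]
    out = []
    for name in ("helix", "turn", "sheet"):
        out.append(sum(1 for ch in residues if ch in classes[name]) / len(residues))
    return tuple(out)


# ---------------------------------------------------------------------------
# metric oracles
# ---------------------------------------------------------------------------

def metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Direct arithmetic evaluation of the six threshold metrics."""
    out = {}
    out["SP"] = tn / (tn + fp) if tn + fp else 0.0
    out["ACC"] = (tn + tp) / (tp + fn + tn + fp) if tp + fn + tn + fp else 0.0
    out["SEN"] = tp / (tp + fn) if tp + fn else 0.0
    out["precision"] = tp / (tp + fp) if tp + fp else 0.0
    p, s = out["precision"], out["SEN"]
    out["F1"] = 2 * p * s / (p + s) if p + s else 0.0
    den = math.sqrt((fp + tp) * (fn + tp) * (tn + fp) * (fn + tn))
    out["MCC"] = (tp * tn - fp * fn) / den if den else 0.0
    return out


def auc_mann_whitney(labels, scores) -> float:
    """AUC as the pairwise-comparison statistic over all pos/neg pairs."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
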