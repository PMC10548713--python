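"""Peptide-window feature encoders.

Each 11-residue window (length ``2*gamma + 1`` in general) is mapped to a
434-dimensional vector laid out in four fixed blocks:

====== ========= ====================================================
block  positions contents
====== ========= ====================================================
AAC    1-20      amino-acid composition, count / window length
DPC    21-420    dipeptide composition over the 400 ordered pairs,
                 adjacent-pair count / window length
ITB    421-424   information-theory features: Shannon (SE),
                 Havrda-Charvat (HE), Renyi (RE) and Arimoto (AE)
                 entropy of the window's residue distribution
PP     425-434   ProtParam-style physicochemical descriptors:
                 pI, MW, aromaticity, instability index, GRAVY,
                 extinction coefficient (reduced / oxidized cystine),
                 helix, turn and sheet fractions
====== ========= ====================================================

The pad character ``'X'`` is inert everywhere: it contributes nothing to any
count, and the physicochemical descriptors are computed over the de-padded
residue string.  Composition denominators use the full window length ``l``
(including pads) so that terminal windows remain comparable to internal ones.

The generalized entropies (HE, RE, AE) take an order parameter ``alpha > 0``,
``alpha != 1`` (all three converge to SE as ``alpha -> 1`` for a proper
distribution); the relative forms compare against a uniform background
``p0 = 1/20``.  Logarithms are base 2 throughout, so entropies are in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants
from .sequence_io import PAD, LabeledDataset, PeptideWindow, POSITIVE

AA = constants.AA_ALPHABET  # alphabetical one-letter codes

# half-open [start, stop) column ranges of the four blocks in the full vector
BLOCKS: dict[str, tuple[int, int]] = {
    "AAC": (0, 20),
    "DPC": (20, 420),
    "ITB": (420, 424),
    "PP": (424, 434),
}
N_FEATURES = 434

_PP_NAMES = [
    "PP_pI", "PP_MW", "PP_AROM", "PP_II", "PP_GRAVY",
    "PP_EX_RED", "PP_EX_OX", "PP_HELIX", "PP_TURN", "PP_SHEET",
]


@dataclass(frozen=True)
class EntropyParams:
    """Parameters of the generalized-entropy features.

    alpha
        Order of the Renyi / Havrda-Charvat / Arimoto entropies; must be
        positive and different from 1.  Default 2 (collision entropy).
    p0
        Uniform background probability used by the relative forms.
    """

    alpha: float = 2.0
    p0: float = 1.0 / 20.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.alpha == 1:
            raise ValueError(f"alpha must be > 0 and != 1, got {self.alpha}")
        if not (0 < self.p0 < 1):
            raise ValueError(f"p0 must be in (0, 1), got {self.p0}")


@dataclass(frozen=True)
class CompositionProfile:
    """Residue probabilities of one window (pad contributes zero numerator)."""

    probabilities: np.ndarray  # 20 floats, alphabetical order, sum <= 1
    effective_length: int  # number of non-pad residues


def _residues(window: PeptideWindow | str) -> str:
    """Encoders accept bare strings too, so tests can probe non-R-centered input."""
    return window.residues if isinstance(window, PeptideWindow) else window


def composition_profile(window: PeptideWindow | str) -> CompositionProfile:
    seq = _residues(window)
    counts = np.array([seq.count(a) for a in AA], dtype=float)
    return CompositionProfile(
        probabilities=counts / len(seq),
        effective_length=int(counts.sum()),
    )


def aac(window: PeptideWindow | str) -> np.ndarray:
    """Amino-acid composition: count of each residue / window length."""
    return composition_profile(window).probabilities.copy()


def dpc(window: PeptideWindow | str, denominator: str = "l") -> np.ndarray:
    """Dipeptide composition over the 400 ordered pairs, row-major.

    The denominator is the window length ``l`` (the convention used
    throughout this package); ``denominator="l-1"`` normalizes by the number
    of adjacent pairs instead, for sensitivity checks.  Pairs containing the
    pad character are not counted.
    """
    if denominator not in ("l", "l-1"):
        raise ValueError(f"denominator must be 'l' or 'l-1', got {denominator!r}")
    seq = _residues(window)
    index = {a: i for i, a in enumerate(AA)}
    counts = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        if a != PAD and b != PAD:
            counts[index[a] * 20 + index[b]] += 1
    denom = len(seq) if denominator == "l" else len(seq) - 1
    return counts / denom


def entropy_block(profile: CompositionProfile, params: EntropyParams | None = None) -> dict[str, float]:
    """All nine information-theory quantities of one composition profile.

    Returns SE, relative_SE, information_gain, HE, relative_HE, RE,
    relative_RE, AE and relative_AE, in bits.  Zero-probability terms are
    omitted (the ``0 * log 0 = 0`` convention); an empty profile yields zeros.
    """
    params = params or EntropyParams()
    a, p0 = params.alpha, params.p0
    p = profile.probabilities
    p = p[p > 0]
    if p.size == 0:
        return {k: 0.0 for k in (
            "SE", "relative_SE", "information_gain",
            "HE", "relative_HE", "RE", "relative_RE", "AE", "relative_AE",
        )}
    se = float(-np.sum(p * np.log2(p)))
    rel_se = float(np.sum(p * np.log2(p / p0)))
    s_alpha = float(np.sum(p ** a))  # sum p_i^alpha
    s_alpha_rel = s_alpha / p0 ** (a - 1)
    s_inv = float(np.sum(p ** (1.0 / a)))  # sum p_i^(1/alpha)
    c_he = 1.0 / (2.0 ** (1.0 - a) - 1.0)
    c_ae = 1.0 / (2.0 ** (a - 1.0) - 1.0)
    # (sum p_i^(1/alpha) / p0^(1/(alpha-1)))^alpha explodes as alpha -> 1;
    # evaluate in log2 space and saturate to +/- inf rather than overflow
    log2_inner = a * (math.log2(s_inv) - math.log2(p0) / (a - 1.0))
    if log2_inner > 1023.0:
        rel_ae_pow = math.inf
    elif log2_inner < -1074.0:
        rel_ae_pow = 0.0
    else:
        rel_ae_pow = 2.0 ** log2_inner
    return {
        "SE": se,
        "relative_SE": rel_se,
        "information_gain": se - rel_se,
        "HE": c_he * (s_alpha - 1.0),
        "relative_HE": -c_he * (s_alpha_rel - 1.0),
        "RE": math.log2(s_alpha) / (1.0 - a),
        "relative_RE": math.log2(s_alpha_rel) / (1.0 - a),
        "AE": c_ae * (s_inv ** a - 1.0),
        "relative_AE": -c_ae * (rel_ae_pow - 1.0),
    }


def itb_features(window: PeptideWindow | str, params: EntropyParams | None = None) -> np.ndarray:
    """The 4-entry entropy block [SE, HE, RE, AE] of the window.

    The relative forms and the information gain are available through
    :func:`entropy_block` but are not part of the 434-vector.
    """
    block = entropy_block(composition_profile(window), params)
    return np.array([block["SE"], block["HE"], block["RE"], block["AE"]])


# ---------------------------------------------------------------------------
# physicochemical descriptors (computed over the de-padded residue string)
# ---------------------------------------------------------------------------

def _depad(window: PeptideWindow | str) -> str:
    return _residues(window).replace(PAD, "")


def extinction_coefficient(window: PeptideWindow | str, oxidized: bool = False) -> float:
    """Molar extinction coefficient at 280 nm (M^-1 cm^-1).

    Sums the Trp and Tyr contributions; with ``oxidized=True`` every cysteine
    pair is assumed to form a cystine bridge (``floor(nC / 2)`` cystines).
    """
    seq = _depad(window)
    me = constants.extinction_coefficients()
    n_cystine = seq.count("C") // 2 if oxidized else 0
    return me["Trp"] * seq.count("W") + me["Tyr"] * seq.count("Y") + me["cystine"] * n_cystine


def instability_index(window: PeptideWindow | str) -> float:
    """Guruprasad instability index, ``10/L * sum(DIWV)`` over adjacent pairs.

    ``L`` is the non-pad length; pairs containing a pad are skipped.  Values
    above 40 predict an unstable protein in vitro (see :func:`is_unstable`).
    """
    seq = _residues(window)
    L = len(seq) - seq.count(PAD)
    if L < 2:
        raise ValueError(f"instability index needs >= 2 non-pad residues, got {L}")
    table = constants.diwv()
    total = sum(table[a + b] for a, b in zip(seq, seq[1:]) if a != PAD and b != PAD)
    return 10.0 / L * total


def is_unstable(ii_value: float) -> bool:
    """Instability-index decision rule: more than 40 is unstable."""
    return ii_value > 40.0


def gravy(window: PeptideWindow | str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    seq = _depad(window)
    if not seq:
        raise ValueError("GRAVY needs at least one non-pad residue")
    kd = constants.hydropathy()
    return sum(kd[r] for r in seq) / len(seq)


def molecular_weight(window: PeptideWindow | str) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    seq = _depad(window)
    if not seq:
        raise ValueError("molecular weight needs at least one non-pad residue")
    masses = constants.residue_masses()
    w = constants.WATER_MASS
    return sum(masses[r] - w for r in seq) + w


def aromaticity(window: PeptideWindow | str) -> float:
    """Fraction of aromatic residues (F, W, Y) among non-pad residues."""
    seq = _depad(window)
    return sum(seq.count(r) for r in "FWY") / len(seq)


def secondary_structure_fractions(window: PeptideWindow | str) -> tuple[float, float, float]:
    """(helix, turn, sheet) residue-class fractions among non-pad residues."""
    seq = _depad(window)
    classes = constants.secondary_structure_classes()
    n = len(seq)
    return tuple(sum(1 for r in seq if r in classes[c]) / n for c in ("helix", "turn", "sheet"))


def _net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a free peptide at a given pH."""
    pka = constants.pka_set()
    pos_terms = [pka["nterm"].get(seq[0], pka["nterm"]["*"])]
    pos_terms += [pka["pos"][r] for r in seq if r in pka["pos"]]
    neg_terms = [pka["cterm"].get(seq[-1], pka["cterm"]["*"])]
    neg_terms += [pka["neg"][r] for r in seq if r in pka["neg"]]
    charge = sum(1.0 / (1.0 + 10.0 ** (ph - pk)) for pk in pos_terms)
    charge -= sum(1.0 / (1.0 + 10.0 ** (pk - ph)) for pk in neg_terms)
    return charge


def isoelectric_point(window: PeptideWindow | str, tol: float = 0.01) -> float:
    """pH at which the peptide's net charge vanishes, by bisection on [0, 14].

    Uses the Bjellqvist pKa set (side chains plus position-specific terminal
    values) and stops at a pH bracket narrower than *tol* or |charge| < 1e-4.
    """
    seq = _depad(window)
    if not seq:
        raise ValueError("pI needs at least one non-pad residue")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        q = _net_charge(seq, mid)
        if abs(q) < 1e-4:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def pp_features(window: PeptideWindow | str) -> np.ndarray:
    """The 10-entry physicochemical block.

    Order: [pI, MW, aromaticity, instability index, GRAVY, EX_reduced,
    EX_oxidized, helix fraction, turn fraction, sheet fraction].
    """
    helix, turn, sheet = secondary_structure_fractions(window)
    return np.array([
        isoelectric_point(window),
        molecular_weight(window),
        aromaticity(window),
        instability_index(window),
        gravy(window),
        extinction_coefficient(window, oxidized=False),
        extinction_coefficient(window, oxidized=True),
        helix,
        turn,
        sheet,
    ])


# ---------------------------------------------------------------------------
# full vector assembly
# ---------------------------------------------------------------------------

def feature_names(blocks: tuple[str, ...] = ("AAC", "DPC", "ITB", "PP")) -> list[str]:
    """Stable, ordered feature identifiers for the selected blocks."""
    names: list[str] = []
    for block in blocks:
        if block == "AAC":
            names += [f"AAC_{a}" for a in AA]
        elif block == "DPC":
            names += [f"DPC_{a}{b}" for a in AA for b in AA]
        elif block == "ITB":
            names += ["ITB_SE", "ITB_HE", "ITB_RE", "ITB_AE"]
        elif block == "PP":
            names += list(_PP_NAMES)
        else:
            raise ValueError(f"unknown feature block {block!r}")
    return names


def encode_window(
    window: PeptideWindow | str,
    params: EntropyParams | None = None,
    blocks: tuple[str, ...] = ("AAC", "DPC", "ITB", "PP"),
    dpc_denominator: str = "l",
) -> np.ndarray:
    """Encode one window as the concatenation of the selected feature blocks.

    With all four blocks (the default) the result has exactly 434 entries in
    the order given by :func:`feature_names`.
    """
    parts = []
    for block in blocks:
        if block == "AAC":
            parts.append(aac(window))
        elif block == "DPC":
            parts.append(dpc(window, denominator=dpc_denominator))
        elif block == "ITB":
            parts.append(itb_features(window, params))
        elif block == "PP":
            parts.append(pp_features(window))
        else:
            raise ValueError(f"unknown feature block {block!r}")
    return np.concatenate(parts)


def encode_dataset(
    dataset: LabeledDataset,
    params: EntropyParams | None = None,
    blocks: tuple[str, ...] = ("AAC", "DPC", "ITB", "PP"),
    dpc_denominator: str = "l",
) -> pd.DataFrame:
    """Encode every window of a dataset into a feature matrix.

    Returns a DataFrame indexed by ``window_id`` whose first column is the
    binary ``label`` (1 = positive) followed by the selected feature columns.
    """
    names = feature_names(blocks)
    rows = np.empty((len(dataset), len(names)))
    ids, labels = [], []
    for i, w in enumerate(dataset):
        rows[i] = encode_window(w, params, blocks, dpc_denominator)
        ids.append(w.window_id)
        labels.append(1 if w.label == POSITIVE else 0)
    df = pd.DataFrame(rows, columns=names, index=pd.Index(ids, name="window_id"))
    df.insert(0, "label", labels)
    return df


def split_matrix(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split an encoded DataFrame into (X, y, feature_names)."""
    names = [c for c in df.columns if c != "label"]
    return df[names].to_numpy(), df["label"].to_numpy(), names
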