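"""Sliding-window amino-acid-scale profiles of protein sequences.

Used to characterise protein termini (e.g. the variable C-terminal end of
Cox1): each residue's score is the unweighted mean of a per-amino-acid scale
over a window centred on it, and profiles are min-max normalised to [0, 1]
so that higher means more accessible under the default scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AAScale",
    "JANIN_ACCESSIBILITY",
    "JANIN_TRANSFER_ENERGY",
    "windowed_profile",
    "normalize_profile",
    "DegenerateProfileError",
]

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class AAScale:
    """A numerical per-amino-acid scale (all 20 standard residues required)."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = _AA20 - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name}: missing residues {sorted(missing)}")


#: Janin (1979): molar fraction (%) of accessible residues, as distributed
#: with the ProtScale collection. Higher = more often solvent-accessible.
JANIN_ACCESSIBILITY = AAScale(
    name="Janin 1979 accessibility",
    values={
        "A": 6.6, "R": 4.5, "N": 6.7, "D": 7.7, "C": 0.9,
        "Q": 5.2, "E": 5.7, "G": 6.7, "H": 2.5, "I": 2.8,
        "L": 4.8, "K": 10.3, "M": 1.0, "F": 2.4, "P": 4.8,
        "S": 9.4, "T": 7.0, "W": 1.4, "Y": 5.1, "V": 4.5,
    },
)

#: Janin (1979): free energy of transfer from protein interior to surface
#: (kcal/mol). Higher = more buried; the hydrophobicity-style companion scale.
JANIN_TRANSFER_ENERGY = AAScale(
    name="Janin 1979 transfer energy",
    values={
        "A": 0.3, "R": -1.4, "N": -0.5, "D": -0.6, "C": 0.9,
        "Q": -0.7, "E": -0.7, "G": 0.3, "H": -0.1, "I": 0.7,
        "L": 0.5, "K": -1.8, "M": 0.4, "F": 0.5, "P": -0.3,
        "S": -0.1, "T": -0.2, "W": 0.3, "Y": -0.4, "V": 0.6,
    },
)


class UnknownResidueError(KeyError):
    """A residue (other than X) has no value on the chosen scale."""


def windowed_profile(
    protein: str,
    scale: AAScale = JANIN_ACCESSIBILITY,
    window: int = 9,
    edge_mode: str = "full_weight_truncated",
) -> list[float]:
    """Per-position mean of scale values over a centred window.

    With ``full_weight_truncated`` (the "fully weighted edges" convention of
    profile tools) windows near the termini truncate to the residues that
    exist, every included residue at weight 1, so the profile has one score
    per residue. ``interior_only`` instead reports only positions with a
    complete window. 'X' residues are skipped and the window mean is taken
    over the remaining residues.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    seq = protein.upper()
    if not seq:
        raise ValueError("empty protein")
    vals = []
    for aa in seq:
        if aa == "X":
            vals.append(np.nan)
        elif aa in scale.values:
            vals.append(scale.values[aa])
        else:
            raise UnknownResidueError(f"residue {aa!r} not on scale {scale.name!r}")
    vals = np.array(vals, dtype=float)
    half = window // 2
    scores: list[float] = []
    if edge_mode == "full_weight_truncated":
        positions = range(len(seq))
    elif edge_mode == "interior_only":
        positions = range(half, len(seq) - half)
    else:
        raise ValueError(f"unknown edge_mode {edge_mode!r}")
    for i in positions:
        win = vals[max(0, i - half) : i + half + 1]
        win = win[~np.isnan(win)]
        if win.size == 0:
            raise UnknownResidueError(f"window at position {i + 1} contains only X residues")
        scores.append(float(win.mean()))
    return scores


class DegenerateProfileError(ValueError):
    """A constant profile cannot be min-max normalised."""


def normalize_profile(scores) -> list[float]:
    """Min-max normalise a profile to [0, 1]; idempotent on normalised input."""
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise ValueError("profile needs at least 2 positions")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegenerateProfileError("constant profile has no range to normalise")
    return list((arr - lo) / (hi - lo))
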