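"""Synthetic sumoylation-like datasets with a controllable motif signal.

Real sumoylation sites are enriched for the consensus motif psi-K-x-E/D
(hydrophobic residue, target lysine, any residue, glutamate or aspartate).
The generator emulates that: every window is 41 residues with K at position
21; a positive window carries the motif anchored at the centre (positions
20/22/23, 1-based) with probability ``motif_probability``, all other
positions drawn from a background composition; a negative window is pure
background with the centred motif actively excluded (rejection sampling), so
the classes differ only through the motif. It does not emulate homology
structure, annotation noise, or position-specific composition beyond the
motif, so results on it speak to the pipeline's mechanics, not to real-data
accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from sumosite.seqio import (
    CENTER_POSITION,
    WINDOW_LENGTH,
    PeptideWindow,
    read_sequences,
    windows_from_records,
)

#: Hydrophobic residues eligible for the psi anchor of the consensus motif.
HYDROPHOBIC_RESIDUES = "AFILMPV"
#: Acidic residues for the E/D anchor.
ACIDIC_RESIDUES = "ED"

STANDARD_RESIDUES = "ARNDCEQGHILKMFPSTWYV"
_ALPHABET = STANDARD_RESIDUES + "X"

# 0-based window indices of the motif anchors psi-K-x-E/D
# (1-based positions 20 and 23; K sits at 1-based 21, "x" at 22)
_PSI_IDX = CENTER_POSITION - 2   # 0-based 19
_ED_IDX = CENTER_POSITION + 1    # 0-based 22


def _uniform_background() -> np.ndarray:
    bg = np.zeros(21)
    bg[:20] = 1.0 / 20.0
    return bg


@dataclass
class SyntheticConfig:
    """Generation settings; defaults give a strongly learnable dataset."""

    n_positive: int = 1000
    n_negative: int = 1000
    motif_probability: float = 0.8
    background: np.ndarray = field(default_factory=_uniform_background)
    window_length: int = WINDOW_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.motif_probability <= 1.0:
            raise ValueError("motif_probability must lie in [0, 1]")
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (21,) or (self.background < 0).any():
            raise ValueError("background must be 21 non-negative frequencies")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if self.window_length != WINDOW_LENGTH:
            raise ValueError(f"window_length is fixed at {WINDOW_LENGTH}")


def _has_centred_motif(window: np.ndarray) -> bool:
    return (
        _ALPHABET[window[_PSI_IDX]] in HYDROPHOBIC_RESIDUES
        and _ALPHABET[window[_ED_IDX]] in ACIDIC_RESIDUES
    )


def generate(config: SyntheticConfig) -> tuple[list[PeptideWindow], np.ndarray]:
    """Draw labelled windows; bit-reproducible under ``config.seed``.

    Returns ``(windows, labels)`` with positives first (label 1), then
    negatives (label 0).
    """
    rng = np.random.default_rng(config.seed)
    k_idx = CENTER_POSITION - 1
    psi_codes = [STANDARD_RESIDUES.index(c) for c in HYDROPHOBIC_RESIDUES]
    ed_codes = [STANDARD_RESIDUES.index(c) for c in ACIDIC_RESIDUES]

    def draw_background() -> np.ndarray:
        w = rng.choice(21, size=WINDOW_LENGTH, p=config.background)
        w[k_idx] = _ALPHABET.index("K")
        return w

    windows: list[PeptideWindow] = []
    for i in range(config.n_positive):
        w = draw_background()
        if rng.random() < config.motif_probability:
            w[_PSI_IDX] = rng.choice(psi_codes)
            # position 22 ("x") stays a background draw
            w[_ED_IDX] = rng.choice(ed_codes)
        windows.append(
            PeptideWindow(
                source_id=f"synthetic_pos_{i + 1}",
                center_position=CENTER_POSITION,
                residues="".join(_ALPHABET[c] for c in w),
                label=1,
            )
        )
    for i in range(config.n_negative):
        w = draw_background()
        while _has_centred_motif(w):
            w = draw_background()
        windows.append(
            PeptideWindow(
                source_id=f"synthetic_neg_{i + 1}",
                center_position=CENTER_POSITION,
                residues="".join(_ALPHABET[c] for c in w),
                label=0,
            )
        )
    labels = np.array([1] * config.n_positive + [0] * config.n_negative, dtype=int)
    return windows, labels


def write_supplementary_style(
    windows: Sequence[PeptideWindow],
    labels: Sequence[int] | np.ndarray,
    directory: str | Path,
    config: SyntheticConfig | None = None,
) -> dict[str, Path]:
    """Write peptide-lines files (one per class) plus a manifest JSON.

    The layout mirrors published supplementary sequence files: bare 41-mer
    windows, one per line, split into a positive and a negative file. Files
    round-trip through :func:`sumosite.seqio.read_sequences`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels, dtype=int)
    if labels.size != len(windows):
        raise ValueError("windows and labels differ in length")
    paths = {
        "positive": directory / "positive_sequences.txt",
        "negative": directory / "negative_sequences.txt",
    }
    for name, wanted in (("positive", 1), ("negative", 0)):
        lines = [w.residues for w, l in zip(windows, labels) if l == wanted]
        paths[name].write_text("\n".join(lines) + ("\n" if lines else ""))
    manifest = {
        "n_positive": int((labels == 1).sum()),
        "n_negative": int((labels == 0).sum()),
        "files": {k: str(v) for k, v in paths.items()},
    }
    if config is not None:
        cfg = asdict(config)
        cfg["background"] = config.background.tolist()
        manifest["config"] = cfg
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = manifest_path
    return paths


def load_supplementary_style(directory: str | Path) -> tuple[list[PeptideWindow], np.ndarray]:
    """Read back a dataset written by :func:`write_supplementary_style`."""
    directory = Path(directory)
    pos = windows_from_records(
        read_sequences(directory / "positive_sequences.txt", format="peptide-lines"),
        label=1,
    )
    neg = windows_from_records(
        read_sequences(directory / "negative_sequences.txt", format="peptide-lines"),
        label=0,
    )
    labels = np.array([1] * len(pos) + [0] * len(neg), dtype=int)
    return pos + neg, labels
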