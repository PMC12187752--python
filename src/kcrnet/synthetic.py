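"""Seeded generator of labeled peptide-window datasets with a planted motif.

Positives carry a position-specific residue preference (a mixture of a sharp
consensus and the background distribution) at a few offsets flanking the
central K; negatives are pure background.  Both classes have K at the
center.  Because the two generative distributions are fully known and the
positions independent, the Bayes-optimal accuracy of the planted model has a
closed form (``expected_separability``), which anchors what a trained
classifier can and cannot achieve on this data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kcrnet.windows import AMINO_ACIDS, LabeledDataset, PeptideWindow

__all__ = ["SyntheticConfig", "generate", "expected_separability",
           "NATURAL_AA_FREQS"]

# Approximate residue frequencies in UniProt/Swiss-Prot, order ACDEFGHIKLMNPQRSTVWY
NATURAL_AA_FREQS = np.array([
    0.0826, 0.0139, 0.0546, 0.0672, 0.0387, 0.0708, 0.0228, 0.0593, 0.0580,
    0.0965, 0.0241, 0.0406, 0.0474, 0.0394, 0.0553, 0.0664, 0.0535, 0.0687,
    0.0110, 0.0292,
])
NATURAL_AA_FREQS = NATURAL_AA_FREQS / NATURAL_AA_FREQS.sum()


@dataclass
class SyntheticConfig:
    n_pos: int = 1000
    n_neg: int = 1000
    window_length: int = 29
    # offsets relative to the central K carrying the motif signal
    motif_positions: tuple[int, ...] = (-2, -1, 1, 2)
    motif_strength: float = 0.9
    background_freqs: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length < 3 or self.window_length % 2 == 0:
            raise ValueError("window_length must be odd and >= 3")
        if not (0.0 <= self.motif_strength <= 1.0):
            raise ValueError("motif_strength must be in [0, 1]")
        bg = np.asarray(self.background_freqs, dtype=np.float64)
        if bg.shape != (20,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background_freqs must be a 20-vector of probabilities summing to 1")
        self.background_freqs = bg / bg.sum()
        half = self.window_length // 2
        for off in self.motif_positions:
            if off == 0 or abs(off) > half:
                raise ValueError(f"motif offset {off} outside the window flanks (or 0)")

    def consensus_residue(self, offset: int) -> str:
        """Deterministic consensus letter for a motif offset (seed-independent)."""
        return AMINO_ACIDS[abs(offset) * 7 % 20]

    def positive_position_freqs(self, offset: int) -> np.ndarray:
        """Residue distribution at a motif offset in the positive class."""
        onehot = np.zeros(20)
        onehot[AMINO_ACIDS.index(self.consensus_residue(offset))] = 1.0
        return self.motif_strength * onehot + (1.0 - self.motif_strength) * self.background_freqs


def generate(config: SyntheticConfig) -> LabeledDataset:
    """Draw n_pos motif-bearing and n_neg background windows, deterministically
    for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    half = config.window_length // 2
    aa = np.array(list(AMINO_ACIDS))
    ds = LabeledDataset()
    for label, n in (("positive", config.n_pos), ("negative", config.n_neg)):
        for i in range(n):
            chars = aa[rng.choice(20, size=config.window_length, p=config.background_freqs)]
            chars[half] = "K"
            if label == "positive":
                for off in config.motif_positions:
                    p = config.positive_position_freqs(off)
                    chars[half + off] = aa[rng.choice(20, p=p)]
            ds.windows.append(
                PeptideWindow(
                    residues="".join(chars),
                    label=label,
                    source_id=f"synth_{label[:3]}_{i}",
                )
            )
    return ds


def expected_separability(config: SyntheticConfig) -> float:
    """Bayes-optimal accuracy of the planted two-class model (equal priors).

    Non-motif positions are identically distributed in both classes and
    cancel from the likelihood ratio, so only the motif positions matter.
    The per-position log-likelihood-ratio distributions are convolved exactly
    (positions are independent) and the optimal rule's accuracy is
    0.5 * sum_x max(P(x), Q(x)), with ties contributing half.
    """
    # distribution of the LLR as {rounded llr: (prob under P, prob under Q)}
    dist: dict[float, tuple[float, float]] = {0.0: (1.0, 1.0)}
    for off in config.motif_positions:
        p = config.positive_position_freqs(off)
        q = config.background_freqs
        new: dict[float, tuple[float, float]] = {}
        for llr, (pP, pQ) in dist.items():
            for pa, qa in zip(p, q):
                if pa == 0.0 and qa == 0.0:
                    continue
                if qa == 0.0:
                    step = np.inf
                elif pa == 0.0:
                    step = -np.inf
                else:
                    step = np.log(pa / qa)
                key = round(llr + step, 10)
                aP, aQ = new.get(key, (0.0, 0.0))
                new[key] = (aP + pP * pa, aQ + pQ * qa)
        dist = new
    acc = 0.0
    for llr, (pP, pQ) in dist.items():
        if llr > 0:
            acc += pP
        elif llr < 0:
            acc += pQ
        else:
            acc += 0.5 * (pP + pQ)
    return 0.5 * acc
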