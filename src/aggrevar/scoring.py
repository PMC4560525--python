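"""Stand-in per-residue aggregation-propensity scorer.

The downstream analysis (APR calling, gatekeeper flanks, domain signatures,
the combined stability rule) consumes only a per-residue percent-scale track;
it is agnostic to which predictor produced it. Externally computed tracks can
be imported via :func:`aggrevar.datamodel.read_track` and always take
precedence. This module supplies a simple, documented scorer so the pipeline
runs end-to-end without an external predictor: each residue's score is a
logistic transform of a centered-window combination of Kyte–Doolittle
hydrophobicity, Chou–Fasman beta-sheet propensity (each min-max normalized
over the 20 residues) and a net-charge magnitude penalty. It is explicitly
not a reimplementation of any published statistical-mechanics predictor.

Edge windows are truncated at the sequence termini and renormalized by their
actual width; no padding residues are invented.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datamodel import ProteinRecord, ScoreTrack, Variant

# Kyte-Doolittle hydropathy index
_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Chou-Fasman beta-sheet conformational preference P(beta)
_CHOU_FASMAN_BETA = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.10,
    "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60, "L": 1.30, "K": 0.74,
    "M": 1.05, "F": 1.38, "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37,
    "Y": 1.47, "V": 1.70,
}

# Formal side-chain charges at neutral pH; histidine treated as neutral.
_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}


def _minmax(scale: dict[str, float]) -> dict[str, float]:
    lo, hi = min(scale.values()), max(scale.values())
    return {aa: (v - lo) / (hi - lo) for aa, v in scale.items()}

_HYD_NORM = _minmax(_KYTE_DOOLITTLE)
_BETA_NORM = _minmax(_CHOU_FASMAN_BETA)


@dataclass(frozen=True)
class ScorerConfig:
    """Parameters of the stand-in scorer.

    The defaults were calibrated once so that fully hydrophobic stretches
    score near the top of the percent scale, charged/proline-rich stretches
    score below the 5% APR threshold, and a natural-composition random
    background yields roughly one residue in ten inside an APR. ``window``
    must be odd and at least 5.
    """

    window: int = 7
    w_hyd: float = 1.0
    w_beta: float = 1.0
    w_charge: float = 1.0
    logistic_scale: float = 0.15
    logistic_mid: float = 1.5

    def __post_init__(self) -> None:
        if self.window < 5 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 5")
        vals = [self.w_hyd, self.w_beta, self.w_charge,
                self.logistic_scale, self.logistic_mid]
        if not all(np.isfinite(vals)):
            raise ValueError("scorer weights must be finite")
        if self.logistic_scale <= 0:
            raise ValueError("logistic_scale must be positive")


DEFAULT_SCORER = ScorerConfig()

_CONFIG_KEYS = {
    "scorer.window": ("window", int),
    "scorer.w_hyd": ("w_hyd", float),
    "scorer.w_beta": ("w_beta", float),
    "scorer.w_charge": ("w_charge", float),
    "scorer.logistic_scale": ("logistic_scale", float),
    "scorer.logistic_mid": ("logistic_mid", float),
}


def scorer_config_from_mapping(mapping: dict[str, str]) -> ScorerConfig:
    """Build a config from ``scorer.*`` keys of a key=value mapping."""
    kwargs = {}
    for key, (field, cast) in _CONFIG_KEYS.items():
        if key in mapping:
            kwargs[field] = cast(mapping[key])
    return replace(DEFAULT_SCORER, **kwargs) if kwargs else DEFAULT_SCORER


def _window_stats(values: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncated-window sums and widths at every position.

    Each window is summed independently (direct convolution), so a change
    to one residue changes only the windows containing it, bit for bit —
    prefix-sum tricks would leak rounding noise outside the window.
    """
    L = len(values)
    full = np.convolve(values, np.ones(2 * radius + 1), mode="full")
    sums = full[radius : radius + L]
    idx = np.arange(L)
    lo = np.maximum(0, idx - radius)
    hi = np.minimum(L, idx + radius + 1)
    return sums, (hi - lo).astype(float)


def score_sequence(
    protein: ProteinRecord, config: ScorerConfig = DEFAULT_SCORER
) -> ScoreTrack:
    """Compute the per-residue aggregation-propensity track (percent scale)."""
    seq = protein.sequence
    hyd = np.array([_HYD_NORM[a] for a in seq])
    beta = np.array([_BETA_NORM[a] for a in seq])
    charge = np.array([_CHARGE.get(a, 0.0) for a in seq])
    radius = (config.window - 1) // 2

    hyd_sum, width = _window_stats(hyd, radius)
    beta_sum, _ = _window_stats(beta, radius)
    charge_sum, _ = _window_stats(charge, radius)

    raw = (
        config.w_hyd * hyd_sum / width
        + config.w_beta * beta_sum / width
        - config.w_charge * np.abs(charge_sum) / width
    )
    scores = 100.0 / (1.0 + np.exp(-(raw - config.logistic_mid) / config.logistic_scale))
    return ScoreTrack(protein.protein_id, scores)


def apply_variant(protein: ProteinRecord, variant: Variant) -> ProteinRecord:
    """Return a new record with the single substitution applied."""
    variant.check_against(protein)
    seq = protein.sequence
    i = variant.position - 1
    return ProteinRecord(protein.protein_id, seq[:i] + variant.mut_aa + seq[i + 1 :])


def mutate_and_rescore(
    protein: ProteinRecord,
    variant: Variant,
    config: ScorerConfig = DEFAULT_SCORER,
) -> tuple[ProteinRecord, ScoreTrack]:
    """Apply one substitution and score the mutant sequence.

    The wild-type inputs are not modified; scores differ from the wild-type
    track only within one window radius of the substituted position.
    """
    mutant = apply_variant(protein, variant)
    return mutant, score_sequence(mutant, config)
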