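"""Ancient-sample authentication summaries.

Chromosomal sex from the ratio of reads mapping to Y versus X+Y (R_Y), and
terminal deamination profiles (C->T at the 5' end, G->A at the 3' end) from
reference-aligned read summaries. Post-mortem cytosine deamination elevates
C->T mismatches at the 5' terminus of authentic ancient reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# R_Y call thresholds: CI entirely below the female bound -> female,
# entirely above the male bound -> male (community-standard cutoffs).
FEMALE_MAX_RY = 0.016
MALE_MIN_RY = 0.075


@dataclass
class SexAssignment:
    n_y: int
    n_x: int
    ry: float
    ci95: tuple[float, float]
    call: str  # female / male / ambiguous

    def to_dict(self) -> dict:
        return {
            "n_y": self.n_y,
            "n_x": self.n_x,
            "ry": self.ry,
            "ci95_lo": self.ci95[0],
            "ci95_hi": self.ci95[1],
            "call": self.call,
        }


@dataclass
class DamageProfile:
    ct_5p: np.ndarray  # C->T rate by position from the 5' end (1..k)
    ga_3p: np.ndarray  # G->A rate by position from the 3' end (1..k)
    n_c_5p: np.ndarray  # reference-C opportunities per position
    n_g_3p: np.ndarray

    @property
    def k(self) -> int:
        return len(self.ct_5p)


def ry_sex(
    n_y: int,
    n_x: int,
    female_max: float = FEMALE_MAX_RY,
    male_min: float = MALE_MIN_RY,
) -> SexAssignment:
    """Sex assignment from X/Y read counts.

    R_Y = nY / (nX + nY) with a normal-approximation 95% CI,
    R_Y +- 1.96*sqrt(R_Y(1-R_Y)/(nX+nY)). Female if the CI lies entirely
    below ``female_max``, male if entirely above ``male_min``, else
    ambiguous.
    """
    total = n_x + n_y
    if total <= 0:
        raise ValueError("need at least one X or Y read")
    ry = n_y / total
    half = 1.96 * np.sqrt(ry * (1.0 - ry) / total)
    lo, hi = ry - half, ry + half
    if hi < female_max:
        call = "female"
    elif lo > male_min:
        call = "male"
    else:
        call = "ambiguous"
    return SexAssignment(n_y, n_x, ry, (lo, hi), call)


def damage_profile(
    reads: list[tuple[str, str]], k: int = 25
) -> DamageProfile:
    """Terminal deamination profile from (read, aligned reference) pairs.

    Position-wise mismatch rates restricted to C->T from the 5' end and
    G->A from the 3' end; positions beyond the shortest informative read
    length are truncated. Rates are mismatches / reference-base
    opportunities.
    """
    if not reads:
        raise ValueError("empty read set")
    max_len = max(len(seq) for seq, _ in reads)
    k = min(k, max_len)
    ct = np.zeros(k)
    n_c = np.zeros(k)
    ga = np.zeros(k)
    n_g = np.zeros(k)
    for seq, ref in reads:
        if len(seq) != len(ref):
            raise ValueError("read and reference strings differ in length")
        length = len(seq)
        for pos in range(min(k, length)):
            if ref[pos] == "C":
                n_c[pos] += 1
                if seq[pos] == "T":
                    ct[pos] += 1
            if ref[length - 1 - pos] == "G":
                n_g[pos] += 1
                if seq[length - 1 - pos] == "A":
                    ga[pos] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ct_rate = np.where(n_c > 0, ct / np.maximum(n_c, 1), 0.0)
        ga_rate = np.where(n_g > 0, ga / np.maximum(n_g, 1), 0.0)
    return DamageProfile(ct_rate, ga_rate, n_c.astype(int), n_g.astype(int))
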