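"""Evolutionary-profile descriptors: PsePSSM, PSSM-AB and PSSM-DWT.

All three consume an L x 20 log-odds profile (one PSI-BLAST PSSM per
protein) and produce a fixed-length vector regardless of L:

* **PsePSSM** — 20 column means of the column-standardized profile plus,
  for each lag t = 1..lag_max, the 20 mean squared differences between
  positions t apart (220 dims at the default lag_max = 10).
* **PSSM-AB** — the profile rows are cut into ``n_blocks`` contiguous
  blocks and each block contributes its 20 column means (400 dims at the
  default 20 blocks).
* **PSSM-DWT** — each column is decomposed with a multi-level discrete
  wavelet transform; the approximation coefficients at every level
  contribute (max, min, mean, std) (320 dims at the default db4 / 4
  levels).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pywt

from .sequence_io import PSSMProfile
from .seq_features import FeatureMatrix


@dataclasses.dataclass
class NormalizedPSSM:
    """Column-standardized profile: each column mean 0, sd 1 (population),
    constant columns mapped to zeros."""

    id: str
    matrix: np.ndarray


def normalize_pssm(profile: PSSMProfile) -> NormalizedPSSM:
    m = profile.matrix
    if m.shape[0] < 2:
        raise ValueError(f"profile {profile.id!r} needs at least 2 positions")
    mean = m.mean(axis=0)
    std = m.std(axis=0)  # population convention
    out = np.where(std < 1e-12, 0.0, (m - mean) / np.where(std < 1e-12, 1.0, std))
    return NormalizedPSSM(id=profile.id, matrix=out)


def encode_psepssm(profile: NormalizedPSSM, lag_max: int = 10) -> np.ndarray:
    """Pseudo-PSSM: 20 column means, then lag-major blocks of 20 values
    theta_{j,t} = (1/(L-t)) * sum_i (m_{i,j} - m_{i+t,j})^2."""
    m = profile.matrix
    L = m.shape[0]
    if L <= lag_max:
        raise ValueError(
            f"profile {profile.id!r} has length {L} <= lag_max={lag_max}"
        )
    parts = [m.mean(axis=0)]
    for t in range(1, lag_max + 1):
        parts.append(((m[:-t] - m[t:]) ** 2).mean(axis=0))
    return np.concatenate(parts)


def encode_pssm_ab(profile: PSSMProfile, n_blocks: int = 20) -> np.ndarray:
    """Average Blocks: per-block column means, block-major; leading blocks
    absorb the remainder when L is not divisible by n_blocks."""
    m = profile.matrix
    if m.shape[0] < n_blocks:
        raise ValueError(
            f"profile {profile.id!r} has {m.shape[0]} rows < n_blocks={n_blocks}"
        )
    return np.concatenate([b.mean(axis=0) for b in np.array_split(m, n_blocks)])


def encode_pssm_dwt(
    profile: PSSMProfile, wavelet: str = "db4", levels: int = 4
) -> np.ndarray:
    """Wavelet statistics: per column, a `levels`-deep DWT cascade
    (symmetric padding); at each level the approximation coefficients
    contribute (max, min, mean, std).  Column-major, level-inner,
    statistic-innermost ordering; d = 20 * levels * 4."""
    m = profile.matrix
    out = np.empty((20, levels, 4))
    for j in range(20):
        approx = m[:, j]
        for lev in range(levels):
            if len(approx) < 2:
                min_len = 2**levels
                raise ValueError(
                    f"profile {profile.id!r} too short for a {levels}-level "
                    f"{wavelet} decomposition; need roughly >= {min_len} positions"
                )
            approx, _detail = pywt.dwt(approx, wavelet, mode="symmetric")
            out[j, lev] = (approx.max(), approx.min(), approx.mean(), approx.std())
    return out.ravel()


def encode_profiles(
    profiles: list[PSSMProfile],
    feature_name: str,
    lag_max: int = 10,
    n_blocks: int = 20,
    wavelet: str = "db4",
    levels: int = 4,
) -> FeatureMatrix:
    """Encode a list of profiles with one PSSM descriptor."""
    if feature_name == "PsePSSM":
        rows = [encode_psepssm(normalize_pssm(p), lag_max) for p in profiles]
    elif feature_name == "PSSM-AB":
        rows = [encode_pssm_ab(p, n_blocks) for p in profiles]
    elif feature_name == "PSSM-DWT":
        rows = [encode_pssm_dwt(p, wavelet, levels) for p in profiles]
    else:
        raise ValueError(f"unknown PSSM feature {feature_name!r}")
    return FeatureMatrix(
        feature_name=feature_name,
        values=np.vstack(rows),
        sample_ids=[p.id for p in profiles],
    )
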