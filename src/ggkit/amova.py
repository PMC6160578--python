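"""One-way analysis of molecular variance (AMOVA) with permutation phi-st.

Sums of squares follow the Excoffier decomposition over squared pairwise
distances: SS_total = sum_{i<j} d2_ij / N, SS_within = sum over groups of
the within-group pair sum divided by the group size, SS_among by
subtraction.  The among-group variance component uses
n0 = (N - sum n_g^2 / N) / (K - 1) and is floored at zero; significance is
assessed by random relabeling of samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .identity_matching import PairDistanceSet


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    ms_among: float
    ms_within: float
    var_among: float
    var_within: float
    phi_st: float
    pct_among: float
    pct_within: float
    perm_p: float
    n_permutations: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": "among_groups", "df": self.df_among, "SS": self.ss_among,
                 "MS": self.ms_among, "variance": self.var_among,
                 "pct": self.pct_among},
                {"source": "within_groups", "df": self.df_within, "SS": self.ss_within,
                 "MS": self.ms_within, "variance": self.var_within,
                 "pct": self.pct_within},
                {"source": "total", "df": self.df_among + self.df_within,
                 "SS": self.ss_total, "MS": np.nan,
                 "variance": self.var_among + self.var_within, "pct": 100.0},
            ]
        )


def _phi_from_ss_within(
    ss_within: np.ndarray, ss_total: float, df_among: int, df_within: int, n0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """phi-st (var_among floored at 0) for a vector of SS_within values."""
    ms_within = ss_within / df_within
    ms_among = (ss_total - ss_within) / df_among
    var_among = np.maximum((ms_among - ms_within) / n0, 0.0)
    var_within = ms_within
    total = var_among + var_within
    phi = np.divide(var_among, total, out=np.zeros_like(var_among), where=total > 0)
    return phi, var_among, var_within


def amova_one_way(
    pairs: PairDistanceSet,
    groups: Mapping[str, str] | Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """One-way AMOVA over squared allele-difference distances.

    ``groups`` maps sample id to group label (or is a label sequence
    aligned with ``pairs.sample_ids``).  The permutation p-value uses the
    +1 correction, (1 + #{permuted phi >= observed}) / (1 + n_permutations),
    so it can never be zero.
    """
    ids = pairs.sample_ids
    if isinstance(groups, Mapping):
        missing = [s for s in ids if s not in groups]
        if missing:
            raise ValidationError(f"samples without a group label: {missing[:5]}")
        labels = np.array([groups[s] for s in ids])
    else:
        if len(groups) != len(ids):
            raise ValidationError("label sequence length must match sample count")
        labels = np.asarray(groups)
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    n = len(ids)
    if k < 2:
        raise ValidationError("AMOVA requires at least 2 groups")
    sizes = np.bincount(inv)
    if (sizes == 0).any():
        raise ValidationError("empty group")
    if not pairs.defined.all():
        raise ValidationError("AMOVA requires complete pairwise distances")

    d2 = pairs.square_matrix("squared")
    np.fill_diagonal(d2, 0.0)
    ss_total = d2.sum() / (2.0 * n)
    df_among = k - 1
    df_within = n - k
    if df_within <= 0:
        raise ValidationError("AMOVA requires N > K")
    n0 = (n - (sizes**2).sum() / n) / df_among

    def ss_within_for(membership: np.ndarray) -> float:
        # membership: (P, N) int matrix of group indices
        out = np.zeros(membership.shape[0])
        for g in range(k):
            z = (membership == g).astype(float)
            out += ((z @ d2) * z).sum(axis=1) / (2.0 * sizes[g])
        return out

    ss_within_obs = float(ss_within_for(inv[None, :])[0])
    phi_obs, va, vw = _phi_from_ss_within(
        np.array([ss_within_obs]), ss_total, df_among, df_within, n0
    )
    phi_obs, va, vw = float(phi_obs[0]), float(va[0]), float(vw[0])

    rng = np.random.default_rng(seed)
    n_ge = 0
    chunk = 256
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perms = rng.permuted(np.tile(inv, (m, 1)), axis=1)
        phi_perm, _, _ = _phi_from_ss_within(
            ss_within_for(perms), ss_total, df_among, df_within, n0
        )
        n_ge += int((phi_perm >= phi_obs).sum())
        done += m
    perm_p = (1 + n_ge) / (1 + n_permutations)

    total_var = va + vw
    pct_within = 100.0 * vw / total_var if total_var > 0 else 100.0
    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_total - ss_within_obs,
        ss_within=ss_within_obs,
        ss_total=ss_total,
        ms_among=(ss_total - ss_within_obs) / df_among,
        ms_within=ss_within_obs / df_within,
        var_among=va,
        var_within=vw,
        phi_st=phi_obs,
        pct_among=100.0 - pct_within,
        pct_within=pct_within,
        perm_p=perm_p,
        n_permutations=n_permutations,
    )


def variance_partition_report(result: AmovaResult) -> pd.DataFrame:
    """Percentage partition of molecular variance (among vs within)."""
    return pd.DataFrame(
        [
            {"component": "among_groups", "variance": result.var_among,
             "pct": result.pct_among},
            {"component": "within_groups", "variance": result.var_within,
             "pct": result.pct_within},
        ]
    )
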