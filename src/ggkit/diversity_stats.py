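"""Per-locus genetic diversity statistics and summaries.

Allele-count agnostic: the same operations work for biallelic SNP panels
and multi-allelic (SSR-style) loci.  Frequencies are computed from observed
allele counts among typed samples.

Formulas (p_i = allele frequencies at one locus, n = typed samples):

* He  = 1 - sum p_i^2 (expected heterozygosity)
* uHe = 2n/(2n-1) * He (unbiased)
* Ne  = 1 / sum p_i^2 (effective allele number; 1/(1-He))
* I   = -sum p_i ln p_i (Shannon information, natural log)
* Ho  = heterozygote fraction among typed samples
* F   = 1 - Ho/He (undefined at monomorphic loci)
* PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2 (Botstein)
* Fnull = (He - Ho)/(He + Ho) (Chakraborty ratio estimator)
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GgkitError, ValidationError
from .genotype_io import GenotypeMatrix

_STAT_COLS = ["Na", "Ne", "MAF", "Ho", "He", "uHe", "I", "F", "PIC", "Fnull"]


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for biallelic genotype counts.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and sums the probabilities of all configurations no
    more probable than the observed one (Wigginton-style).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValidationError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValidationError("no genotypes")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0  # monomorphic: single configuration
    # possible het counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log unnormalized conditional probabilities
    from scipy.special import gammaln

    def lg(x):
        return gammaln(np.asarray(x, dtype=float) + 1.0)

    n_aa_h = (n_a - hets) // 2
    n_bb_h = (n_b - hets) // 2
    logp = hets * np.log(2.0) - (lg(n_aa_h) + lg(hets) + lg(n_bb_h))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_ab][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

def locus_statistics(
    matrix: GenotypeMatrix,
    subset: Sequence[str] | None = None,
    hwe: bool = True,
    bonferroni_alpha: float = 0.05,
) -> pd.DataFrame:
    """Diversity statistics per locus over ``subset`` (default: all samples).

    Returns a DataFrame indexed 0..L-1 with ``locus_id``, ``n_typed`` and
    the statistic columns; F/Fnull are NaN at monomorphic loci, MAF and the
    HWE p-value only populated for loci with <= 2 observed alleles.  Loci
    with zero typed samples get NaN throughout and ``n_typed = 0``.
    """
    if subset is not None:
        if len(subset) == 0:
            raise ValidationError("subset must be non-empty")
        matrix = matrix.subset_samples(subset)
    if matrix.n_samples == 0:
        raise ValidationError("locus statistics need at least one sample")
    rows = []
    calls = matrix.calls
    miss = matrix.missing_mask()
    for j, lid in enumerate(matrix.locus_ids):
        typed = ~miss[:, j]
        n = int(typed.sum())
        row: dict[str, object] = {"locus_id": lid, "n_typed": n}
        if n == 0:
            row.update({c: np.nan for c in _STAT_COLS})
            row["hwe_p"] = np.nan
            rows.append(row)
            continue
        pair = calls[typed, j]
        counts = np.bincount(pair.ravel(), minlength=len(matrix.alleles[j]))
        p = counts[counts > 0] / counts.sum()
        na = len(p)
        sum_p2 = float((p**2).sum())
        he = 1.0 - sum_p2
        ho = float((pair[:, 0] != pair[:, 1]).mean())
        row["Na"] = na
        row["Ne"] = 1.0 / sum_p2
        row["MAF"] = (float(p.min()) if na == 2 else (0.0 if na == 1 else np.nan))
        row["Ho"] = ho
        row["He"] = he
        row["uHe"] = (2 * n / (2 * n - 1)) * he if n > 1 else he
        row["I"] = float(-(p * np.log(p)).sum())
        row["F"] = 1.0 - ho / he if he > 0 else np.nan
        row["PIC"] = he - sum(
            2 * p[i] ** 2 * p[k] ** 2 for i in range(na) for k in range(i + 1, na)
        )
        row["Fnull"] = (he - ho) / (he + ho) if (he + ho) > 0 else np.nan
        if hwe and na <= 2:
            n_hom = np.bincount(pair[pair[:, 0] == pair[:, 1], 0],
                                minlength=len(matrix.alleles[j]))
            n_het = int((pair[:, 0] != pair[:, 1]).sum())
            hom_nz = n_hom[np.nonzero(counts)[0]] if na else n_hom
            if na == 1:
                row["hwe_p"] = 1.0
            else:
                row["hwe_p"] = hwe_exact_test(int(hom_nz[0]), n_het, int(hom_nz[1]))
        else:
            row["hwe_p"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    n_tests = int(df["hwe_p"].notna().sum())
    df["hwe_signif_bonf"] = (
        df["hwe_p"] < (bonferroni_alpha / n_tests) if n_tests else False
    )
    return df


# ---------------------------------------------------------------------------
# summaries and marker-set comparison
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    """Unweighted per-statistic mean/min/max over loci plus band fractions."""

    per_stat: pd.DataFrame  # index: statistic; columns: mean, min, max, n_defined
    monomorphic_fraction: float
    maf_band_fraction: float  # MAF in [0.30, 0.50]
    pic_below_0_1_fraction: float
    pic_ge_0_2_fraction: float

    def to_dataframe(self) -> pd.DataFrame:
        df = self.per_stat.reset_index(names="statistic")
        extra = pd.DataFrame(
            {
                "statistic": [
                    "fraction_monomorphic",
                    "fraction_maf_0.30_0.50",
                    "fraction_pic_lt_0.1",
                    "fraction_pic_ge_0.2",
                ],
                "mean": [
                    self.monomorphic_fraction,
                    self.maf_band_fraction,
                    self.pic_below_0_1_fraction,
                    self.pic_ge_0_2_fraction,
                ],
            }
        )
        return pd.concat([df, extra], ignore_index=True)


def summarize(stats: pd.DataFrame) -> DiversitySummary:
    """Summarize a :func:`locus_statistics` table over loci.

    Means are unweighted over loci where the statistic is defined; band
    fractions use closed interval endpoints and are taken over loci with a
    defined value of the underlying statistic.
    """
    defined = stats[stats["n_typed"] > 0]
    if defined.empty:
        raise ValidationError("no locus has defined statistics")
    per = {}
    for c in _STAT_COLS:
        vals = defined[c].astype(float)
        per[c] = {
            "mean": vals.mean(),
            "min": vals.min(),
            "max": vals.max(),
            "n_defined": int(vals.notna().sum()),
        }
    per_stat = pd.DataFrame(per).T
    mono = float((defined["Na"] == 1).mean())
    maf = defined["MAF"].dropna()
    maf_band = float(((maf >= 0.30) & (maf <= 0.50)).mean()) if len(maf) else np.nan
    pic = defined["PIC"].dropna()
    pic_lo = float((pic < 0.1).mean()) if len(pic) else np.nan
    pic_hi = float((pic >= 0.2).mean()) if len(pic) else np.nan
    return DiversitySummary(per_stat, mono, maf_band, pic_lo, pic_hi)


def compare_marker_sets(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    label_a: str = "set_A",
    label_b: str = "set_B",
    samples_a: Sequence[str] | None = None,
    samples_b: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Side-by-side mean Navg/Ne/Ho/He/I for two marker sets.

    Both statistics tables must describe the same sample subset; when the
    subsets are supplied and share no samples the comparison is refused.
    """
    if samples_a is not None and samples_b is not None:
        if not set(samples_a) & set(samples_b):
            raise GgkitError("marker sets cover disjoint sample subsets")
    rows = []
    for param, col in [("Navg", "Na"), ("Ne", "Ne"), ("Ho", "Ho"),
                       ("He", "He"), ("I", "I")]:
        rows.append(
            {
                "parameter": param,
                label_a: stats_a[col].astype(float).mean(),
                label_b: stats_b[col].astype(float).mean(),
            }
        )
    return pd.DataFrame(rows)
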