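"""Transcription-factor family size statistics and WGD-retention tables.

Family gene counts across species are screened (families with fewer than
10 members in any species, or whose counts fail a Shapiro–Wilk normality
test, are dropped), then the focal species' count is expressed as a
z-score z = (x - mu) / sigma against the cross-species distribution, with
sigma the sample (n-1) standard deviation.  Families with z > 1.5 are
flagged as enlarged.  Separately, per-family retention tables count how
many members fall in the sigma- and rho-retained gene sets and their
union, as a percentage of the family's size in the focal genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .retention import round_half_up_percent


class TFStatsError(ValueError):
    pass


Z_FLAG_THRESHOLD = 1.5


def family_count_matrix(
    tf_tables: Mapping[str, Mapping[str, str]]
) -> pd.DataFrame:
    """Family x species gene-count matrix from per-species gene->family maps.

    A family absent from a species counts 0; a family absent everywhere
    cannot occur (it would have no genes).  A gene listed with two
    different families is an error.
    """
    counts: dict[str, dict[str, int]] = {}
    for species, table in tf_tables.items():
        seen: dict[str, str] = {}
        for gene, family in table.items():
            if gene in seen and seen[gene] != family:
                raise TFStatsError(
                    f"gene {gene!r} assigned to families {seen[gene]!r} and {family!r}"
                )
            seen[gene] = family
            counts.setdefault(family, {}).setdefault(species, 0)
            counts[family][species] += 1
    matrix = pd.DataFrame(counts).T.reindex(columns=sorted(tf_tables)).fillna(0)
    return matrix.astype(int).sort_index()


def screen_families(
    matrix: pd.DataFrame,
    min_members: int = 10,
    alpha_normal: float = 0.05,
) -> pd.DataFrame:
    """Shapiro–Wilk and minimum-size screen of the family count matrix.

    Returns one row per family with W, p_normal, mu, sigma (sample sd) and
    the screening outcome: 'too_few' when any species count is below
    ``min_members``, 'non_normal' when the test rejects at
    ``alpha_normal`` (zero-variance families are screened out here too,
    by convention), empty string when retained.
    """
    if matrix.shape[1] < 3:
        raise TFStatsError("Shapiro-Wilk screening needs at least 3 species")
    rows = []
    for family, counts in matrix.iterrows():
        x = counts.to_numpy(dtype=float)
        W = p = np.nan
        if x.min() < min_members:
            reason = "too_few"
        elif np.ptp(x) == 0.0:
            reason = "non_normal"  # degenerate: zero variance
        else:
            W, p = stats.shapiro(x)
            reason = "non_normal" if p < alpha_normal else ""
        rows.append(
            {
                "family": family,
                "W": W,
                "p_normal": p,
                "mu": x.mean(),
                "sigma": x.std(ddof=1),
                "screened_out": reason,
            }
        )
    return pd.DataFrame(rows).set_index("family")


def zscore(x: float, counts: Iterable[float], ddof: int = 1) -> float:
    """z = (x - mean) / sd with the sample (n-1) standard deviation."""
    arr = np.asarray(list(counts), dtype=float)
    sd = arr.std(ddof=ddof)
    if sd == 0.0:
        raise TFStatsError("zero standard deviation: z-score undefined")
    return float((x - arr.mean()) / sd)


def tf_zscore_table(
    matrix: pd.DataFrame,
    focal_species: str,
    min_members: int = 10,
    alpha_normal: float = 0.05,
    z_threshold: float = Z_FLAG_THRESHOLD,
) -> pd.DataFrame:
    """Screen families and z-score the focal species' family sizes.

    The z-score is defined only for retained families; families with
    z > ``z_threshold`` are flagged as enlarged in the focal genome.
    """
    if focal_species not in matrix.columns:
        raise TFStatsError(f"focal species {focal_species!r} absent from matrix")
    screened = screen_families(matrix, min_members, alpha_normal)
    z = []
    flagged = []
    for family in screened.index:
        if screened.loc[family, "screened_out"]:
            z.append(np.nan)
            flagged.append(False)
        else:
            value = zscore(
                matrix.loc[family, focal_species], matrix.loc[family].to_numpy()
            )
            z.append(value)
            flagged.append(value > z_threshold)
    out = screened.copy()
    out["x_focal"] = matrix[focal_species]
    out["z"] = z
    out["enlarged"] = flagged
    return out


@dataclass
class RetentionRow:
    """One family's WGD-retention counts in the focal genome."""

    family: str
    n_genome: int
    n_sigma: int
    n_rho: int
    n_union: int

    def __post_init__(self) -> None:
        if self.n_union > self.n_sigma + self.n_rho:
            raise TFStatsError(f"{self.family}: union exceeds sigma + rho")
        if max(self.n_sigma, self.n_rho, self.n_union) > self.n_genome:
            raise TFStatsError(f"{self.family}: retained count exceeds family size")

    @property
    def fraction_union(self) -> float:
        return round_half_up_percent(self.n_union, self.n_genome)


def retention_table(
    tf_table: Mapping[str, str],
    sigma_set: set[str],
    rho_set: set[str],
) -> list[RetentionRow]:
    """Per-family retained counts from the focal genome's gene->family map."""
    families: dict[str, list[str]] = {}
    for gene, family in tf_table.items():
        families.setdefault(family, []).append(gene)
    rows = []
    for family in sorted(families):
        members = set(families[family])
        rows.append(
            RetentionRow(
                family=family,
                n_genome=len(members),
                n_sigma=len(members & sigma_set),
                n_rho=len(members & rho_set),
                n_union=len(members & (sigma_set | rho_set)),
            )
        )
    return rows


def retention_rows_from_counts(
    counts: Mapping[str, tuple[int, int]] | Mapping[str, tuple[int, int, int, int]]
) -> list[RetentionRow]:
    """Build retention rows from printed per-family totals.

    ``counts`` maps family -> (n_genome, n_union) or
    (n_genome, n_union, n_sigma, n_rho).
    """
    rows = []
    for family in counts:
        values = counts[family]
        if len(values) == 2:
            n_genome, n_union = values
            n_sigma = n_rho = n_union  # unknown split; satisfies invariants
        else:
            n_genome, n_union, n_sigma, n_rho = values
        rows.append(RetentionRow(family, n_genome, n_sigma, n_rho, n_union))
    return rows


def retention_fraction_range(rows: Iterable[RetentionRow]) -> tuple[float, float]:
    """Min and max union-retention percentage across families."""
    fractions = [row.fraction_union for row in rows]
    if not fractions:
        raise TFStatsError("no retention rows")
    return min(fractions), max(fractions)


def retention_table_frame(rows: Iterable[RetentionRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "n_genome": r.n_genome,
                "n_sigma": r.n_sigma,
                "n_rho": r.n_rho,
                "n_union": r.n_union,
                "fraction_union": r.fraction_union,
            }
            for r in rows
        ]
    )
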