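"""Label-free Hi3 protein quantification from a peptide intensity table.

The Hi3 (top-3) estimator scores a protein in one biological replicate as
the summed intensity of its three most intense peptides, after modified
peptides are discarded and each replicate is normalized by division through
its median peptide intensity.  A protein is accepted for quantification
only when a Hi3 value exists in at least two of three replicates (for n
replicates: ceil(2n/3), overridable), and its relative abundance is its
Hi3 value divided by the summed Hi3 of all quantifiable proteins in that
replicate.

The expected input is a long-format table with columns ``protein_id,
peptide_seq, is_modified, strain_id, replicate_id, intensity`` (one row per
peptide observation in one biological replicate of one strain).  An import
shim maps the common search-engine peptide export (``Sequence`` /
``Proteins`` / ``Modifications`` / per-sample ``Intensity ...`` columns)
onto this dialect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_KEYS = ["strain_id", "replicate_id"]


@dataclass(frozen=True)
class RelativeAbundance:
    """Relative abundance of one protein in one strain.

    ``fractions`` maps replicate id to the protein's share of the summed
    Hi3 intensity of all quantifiable proteins in that replicate; ``mean``
    and ``sd`` summarize across replicates.  ``quantifiable`` is False when
    the protein failed the replicate filter in this strain, in which case
    the numeric fields are NaN rather than zero.
    """

    protein_id: str
    strain_id: str
    fractions: Mapping[str, float]
    mean: float
    sd: float
    quantifiable: bool


def load_peptide_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_modified"] = df["is_modified"].astype(bool)
    return df


def from_search_engine(
    df: pd.DataFrame,
    sample_map: Mapping[str, tuple[str, str]],
    intensity_prefix: str = "Intensity ",
) -> pd.DataFrame:
    """Map a wide search-engine peptide table onto the long dialect.

    ``sample_map`` assigns each sample name (the suffix of an
    ``Intensity <sample>`` column) to a ``(strain_id, replicate_id)`` pair.
    Shared accessions are resolved by taking the leading entry of the
    semicolon-separated ``Proteins`` field as given; rows whose
    ``Modifications`` field is anything other than ``Unmodified`` are
    flagged modified.  Zero intensities are treated as unreported and
    dropped.
    """
    rows = []
    for _, row in df.iterrows():
        protein = str(row["Proteins"]).split(";")[0]
        modified = str(row.get("Modifications", "Unmodified")) != "Unmodified"
        for sample, (strain, rep) in sample_map.items():
            col = intensity_prefix + sample
            if col not in df.columns:
                raise KeyError(f"missing column {col!r}")
            intensity = row[col]
            if pd.isna(intensity) or intensity <= 0:
                continue
            rows.append(
                (protein, row["Sequence"], modified, strain, rep, float(intensity))
            )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "peptide_seq", "is_modified", "strain_id", "replicate_id", "intensity"],
    )


def filter_modified(records: pd.DataFrame) -> pd.DataFrame:
    """Discard modified peptide rows."""
    return records.loc[~records["is_modified"].astype(bool)].reset_index(drop=True)


def _drop_unreported(records: pd.DataFrame) -> pd.DataFrame:
    # zero and missing intensities both mean "not reported"
    present = records["intensity"].notna() & (records["intensity"] > 0)
    return records.loc[present]


def median_normalize(records: pd.DataFrame) -> pd.DataFrame:
    """Divide each reported intensity by the median of its replicate.

    The median is taken over all reported intensities of one biological
    replicate (one ``strain_id, replicate_id`` sample), with the even-count
    median equal to the mean of the two middle values.  Replicates with no
    reported intensity contribute no rows and are logged.
    """
    records = _drop_unreported(records)
    if records.empty:
        logger.warning("median_normalize: no reported intensities in any replicate")
        return records.assign(norm_intensity=pd.Series(dtype=float))
    medians = records.groupby(SAMPLE_KEYS)["intensity"].transform("median")
    return records.assign(norm_intensity=records["intensity"] / medians).reset_index(
        drop=True
    )


def hi3_per_replicate(
    normalized: pd.DataFrame, min_peptides: int = 3
) -> pd.DataFrame:
    """Per (strain, replicate, protein) Hi3 value.

    The Hi3 value is the sum of the ``min_peptides`` (default 3) largest
    normalized peptide intensities; proteins with fewer reported peptides in
    a replicate get no value there.  Ties at the cut are interchangeable:
    the sum of the three largest values is unaffected by row order.
    """
    def top_sum(values: pd.Series) -> float:
        if len(values) < min_peptides:
            return np.nan
        return float(np.sort(values.to_numpy())[-min_peptides:].sum())

    out = (
        normalized.groupby(SAMPLE_KEYS + ["protein_id"])["norm_intensity"]
        .apply(top_sum)
        .rename("hi3")
        .reset_index()
    )
    return out.dropna(subset=["hi3"]).reset_index(drop=True)


def default_min_present(n_replicates: int) -> int:
    """Generalize the two-out-of-three rule: ceil(2n/3) replicates."""
    return math.ceil(2 * n_replicates / 3)


def replicate_filter(
    quants: pd.DataFrame,
    n_replicates: int | None = None,
    min_present: int | None = None,
) -> pd.DataFrame:
    """Flag proteins quantifiable per strain by replicate presence.

    A protein is quantifiable in a strain when its Hi3 value exists in at
    least ``min_present`` replicates (default: ceil(2n/3) of the strain's
    ``n_replicates``, i.e. 2 of 3).  Returns the per-replicate table with a
    ``quantifiable`` column.
    """
    if quants.empty:
        return quants.assign(quantifiable=pd.Series(dtype=bool))
    if n_replicates is None:
        reps_per_strain = quants.groupby("strain_id")["replicate_id"].nunique()
    else:
        reps_per_strain = None
    parts = []
    for strain, grp in quants.groupby("strain_id"):
        n = n_replicates if n_replicates is not None else int(reps_per_strain[strain])
        need = min_present if min_present is not None else default_min_present(n)
        counts = grp.groupby("protein_id")["replicate_id"].nunique()
        ok = counts[counts >= need].index
        parts.append(grp.assign(quantifiable=grp["protein_id"].isin(ok)))
    return pd.concat(parts, ignore_index=True)


def relative_abundance_table(quants: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate relative abundances of all quantifiable proteins.

    Within each replicate the fraction is hi3 / sum(hi3 over quantifiable
    proteins reported in that replicate); fractions in one replicate sum
    to 1.  Requires the ``quantifiable`` column from :func:`replicate_filter`.
    """
    q = quants.loc[quants["quantifiable"]]
    if q.empty:
        return q.assign(fraction=pd.Series(dtype=float))
    totals = q.groupby(SAMPLE_KEYS)["hi3"].transform("sum")
    return q.assign(fraction=q["hi3"] / totals).reset_index(drop=True)


def relative_abundance(
    quants: pd.DataFrame,
    target_protein: str,
    strain_id: str,
    mode: str = "per_replicate",
) -> RelativeAbundance:
    """Relative abundance of one target protein in one strain.

    ``mode='per_replicate'`` (default) computes the fraction in every
    replicate and then averages; ``mode='ratio_of_means'`` divides the mean
    target Hi3 by the mean total Hi3 instead.  A target that is not
    quantifiable yields an explicit not-quantifiable result (NaN fields),
    never zero.
    """
    if mode not in ("per_replicate", "ratio_of_means"):
        raise ValueError(f"unknown mode {mode!r}")
    strain = quants.loc[quants["strain_id"] == strain_id]
    target = strain.loc[
        (strain["protein_id"] == target_protein) & strain["quantifiable"]
    ]
    if target.empty:
        return RelativeAbundance(
            target_protein, strain_id, {}, float("nan"), float("nan"), False
        )
    fractions_df = relative_abundance_table(strain)
    mine = fractions_df.loc[fractions_df["protein_id"] == target_protein]
    fractions = dict(zip(mine["replicate_id"], mine["fraction"]))
    if mode == "per_replicate":
        values = np.array(list(fractions.values()))
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
    else:
        q = strain.loc[strain["quantifiable"]]
        totals = q.groupby("replicate_id")["hi3"].sum()
        mean = float(target["hi3"].mean() / totals.loc[list(fractions)].mean())
        values = np.array(list(fractions.values()))
        sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
    return RelativeAbundance(target_protein, strain_id, fractions, mean, sd, True)


def strain_fold_change(
    rel_a: RelativeAbundance, rel_b: RelativeAbundance
) -> tuple[float, float]:
    """Fold change of relative abundance between two strains (a over b).

    Returns ``(ratio, sd)`` where the standard deviation is propagated from
    the two means' replicate spreads assuming independence:
    sd = ratio * sqrt((sd_a/mean_a)^2 + (sd_b/mean_b)^2).
    """
    if not (rel_a.quantifiable and rel_b.quantifiable):
        raise ValueError("fold change requires the target quantifiable in both strains")
    ratio = rel_a.mean / rel_b.mean
    sd = ratio * math.sqrt(
        (rel_a.sd / rel_a.mean) ** 2 + (rel_b.sd / rel_b.mean) ** 2
    )
    return ratio, sd


def run_pipeline(
    records: pd.DataFrame,
    min_peptides: int = 3,
    n_replicates: int | None = None,
    min_present: int | None = None,
) -> pd.DataFrame:
    """Peptide table -> per-replicate Hi3 + quantifiable flag + fraction.

    Applies, in order: modified-peptide filter, per-replicate median
    normalization, Hi3 with the >=3-peptide rule, the replicate-presence
    filter, and per-replicate relative abundance.
    """
    records = filter_modified(records)
    normalized = median_normalize(records)
    quants = hi3_per_replicate(normalized, min_peptides=min_peptides)
    if quants.empty:
        return quants.assign(
            quantifiable=pd.Series(dtype=bool), fraction=pd.Series(dtype=float)
        )
    quants = replicate_filter(quants, n_replicates=n_replicates, min_present=min_present)
    fractions = relative_abundance_table(quants)
    return quants.merge(
        fractions[SAMPLE_KEYS + ["protein_id", "fraction"]],
        on=SAMPLE_KEYS + ["protein_id"],
        how="left",
    )


def write_quant_table(quants: pd.DataFrame, path) -> None:
    quants.to_csv(path, sep="\t", index=False)
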