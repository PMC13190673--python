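"""Read-count normalizations and abundance-currency bookkeeping.

Three metabarcoding abundance measures are derived from raw ASV reads:

* relative abundance to the whole community (spike reads excluded from
  numerator and denominator),
* spike-normalized absolute marker abundance, A = (r_i / r_spike) *
  (M / V) in molecules per liter, anchored by the known number M of
  spike-in molecules added before extraction,
* DNA-weighted abundance, relative abundance times the DNA yield of the
  extraction (comparative units only).

Spike-normalized values are molecules of marker per liter and are never
converted to cells here: the per-cell gene copy number is unknown and
the conversion is deliberately left to the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AsvTable, ValidationError
from .taxonomy import RANKS

__all__ = [
    "AbundanceMatrix",
    "NormalizationUnavailableError",
    "relative_abundance",
    "spike_normalize",
    "dna_normalize",
    "community_proportions",
    "aggregate_to_rank",
    "equivalent_volume",
    "spike_dispersion",
    "microscopy_matrix",
    "to_long",
]

logger = logging.getLogger(__name__)

CURRENCIES = (
    "reads",
    "relative",
    "molecules_per_liter",
    "dna_weighted",
    "cells_per_liter",
    "biovolume",
    "carbon",
)


class NormalizationUnavailableError(ValueError):
    """The metadata required by a normalization is absent altogether."""


@dataclass(frozen=True)
class AbundanceMatrix:
    """Samples x taxa non-negative abundances in one currency.

    ``flagged_samples`` lists rows that are all-zero (or had a zero
    denominator); ``excluded_samples`` lists samples dropped from this
    normalization (they remain valid for the others).
    """

    data: pd.DataFrame
    currency: str
    rank: str | None = None
    flagged_samples: tuple[str, ...] = ()
    excluded_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.currency not in CURRENCIES:
            raise ValueError(f"unknown currency {self.currency!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("abundances must be >= 0")
        if self.currency == "relative" and len(self.data):
            sums = self.data.sum(axis=1).to_numpy()
            ok = np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12)
            if not ok.all():
                bad = self.data.index[~ok][0]
                raise ValidationError(f"relative row {bad!r} sums to {sums[~ok][0]!r}")


def relative_abundance(asv: AsvTable) -> AbundanceMatrix:
    """Relative read abundance to the whole community, excluding spikes.

    All-zero rows stay zero and are flagged.
    """
    counts = asv.nonspike_counts().astype(float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    out = counts.div(totals.where(~zero, 1.0), axis=0)
    out[zero] = 0.0
    return AbundanceMatrix(out, "relative", flagged_samples=tuple(counts.index[zero]))


def spike_normalize(asv: AsvTable, metadata: pd.DataFrame) -> AbundanceMatrix:
    """Absolute marker abundance in molecules per liter via the spike-in.

    A_{i,s} = (r_{i,s} / r_{spike,s}) * (M_s / V_s). Multiple spike ASVs
    are summed into r_spike. Samples with zero spike reads are excluded
    with a logged warning; a sample lacking M_s while the column exists
    is an error.
    """
    if not asv.spike_asv_ids:
        raise NormalizationUnavailableError("no spike ASVs flagged in the table")
    if "spike_molecules" not in metadata.columns:
        raise NormalizationUnavailableError("metadata has no 'spike_molecules' column")
    meta = metadata.loc[asv.sample_ids]
    if meta["spike_molecules"].isna().any():
        bad = meta.index[meta["spike_molecules"].isna()][0]
        raise ValidationError(f"sample {bad!r} has no spike_molecules value")
    if (meta["spike_molecules"] <= 0).any():
        bad = meta.index[meta["spike_molecules"] <= 0][0]
        raise ValidationError(f"sample {bad!r} has non-positive spike_molecules")
    spike_reads = asv.spike_reads()
    ok = spike_reads > 0
    if not ok.all():
        dropped = list(spike_reads.index[~ok])
        logger.warning(
            "spike normalization: excluding %d sample(s) with zero spike reads: %s",
            len(dropped), dropped,
        )
    counts = asv.nonspike_counts().loc[ok].astype(float)
    factor = (meta.loc[ok, "spike_molecules"] / meta.loc[ok, "volume_filtered"]) / spike_reads[ok]
    out = counts.mul(factor, axis=0)
    return AbundanceMatrix(
        out, "molecules_per_liter",
        excluded_samples=tuple(spike_reads.index[~ok]),
    )


def dna_normalize(asv: AsvTable, metadata: pd.DataFrame, measure: str = "concentration") -> AbundanceMatrix:
    """Relative abundance weighted by DNA yield of the extraction.

    ``measure`` selects the metadata column: "concentration" (ng/ul,
    ``dna_concentration``) or "total" (ng, ``dna_total``). Samples
    missing the value are excluded with a warning; a zero yield gives an
    all-zero flagged row.
    """
    column = {"concentration": "dna_concentration", "total": "dna_total"}.get(measure)
    if column is None:
        raise ValueError(f"unknown DNA measure {measure!r}")
    if column not in metadata.columns:
        raise NormalizationUnavailableError(f"metadata has no {column!r} column")
    rel = relative_abundance(asv)
    d = metadata.loc[asv.sample_ids, column]
    ok = d.notna()
    if not ok.all():
        dropped = list(d.index[~ok])
        logger.warning(
            "DNA normalization: excluding %d sample(s) without %s: %s",
            len(dropped), column, dropped,
        )
    data = rel.data.loc[ok].mul(d[ok], axis=0)
    zero = data.sum(axis=1) == 0
    return AbundanceMatrix(
        data, "dna_weighted",
        flagged_samples=tuple(data.index[zero]),
        excluded_samples=tuple(d.index[~ok]),
    )


def community_proportions(matrix, whitelist) -> AbundanceMatrix:
    """Proportions relative to the defined phytoplankton community.

    Each row is divided by its sum over whitelist classes only;
    non-whitelist columns are dropped. Rows with zero whitelist sum are
    flagged and left all-zero.
    """
    data = matrix.data if isinstance(matrix, AbundanceMatrix) else matrix
    cols = [c for c in data.columns if c in set(whitelist)]
    sub = data[cols].astype(float)
    totals = sub.sum(axis=1)
    zero = totals == 0
    out = sub.div(totals.where(~zero, 1.0), axis=0)
    out[zero] = 0.0
    rank = matrix.rank if isinstance(matrix, AbundanceMatrix) else None
    return AbundanceMatrix(out, "relative", rank=rank,
                           flagged_samples=tuple(sub.index[zero]))


def aggregate_to_rank(matrix, taxonomy: pd.DataFrame, rank: str) -> AbundanceMatrix:
    """Sum columns by their name at ``rank``.

    ``taxonomy`` must cover every column (index = column ids, rank-named
    columns). Columns unassigned at the rank are pooled into a single
    ``unassigned`` column so that row sums are conserved.
    """
    if rank not in RANKS:
        raise KeyError(f"unknown rank {rank!r}")
    if isinstance(matrix, AbundanceMatrix):
        data, currency = matrix.data, matrix.currency
        flagged, excluded = matrix.flagged_samples, matrix.excluded_samples
    else:
        data, currency = matrix, "reads"
        flagged, excluded = (), ()
    missing = set(data.columns) - set(taxonomy.index)
    if missing:
        raise ValidationError(f"taxonomy does not cover columns: {sorted(missing)[:5]}")
    names = taxonomy.loc[list(data.columns), rank].to_numpy()
    out = data.T.groupby(names).sum().T
    out.columns.name = rank
    return AbundanceMatrix(out, currency, rank=rank,
                           flagged_samples=flagged, excluded_samples=excluded)


def equivalent_volume(template_dna_ng: float, total_dna_ng: float,
                      volume_filtered_liters: float) -> float:
    """Seawater volume equivalent analyzed: (template/total) * V_filtered.

    The share of the extract used as PCR template maps onto an
    equivalent volume of the original water sample, the quantity that
    bounds rare-taxon detection.
    """
    if total_dna_ng <= 0 or template_dna_ng < 0:
        raise ValueError("DNA amounts must be positive (template may be 0)")
    if template_dna_ng > total_dna_ng:
        raise ValueError("template DNA exceeds total DNA")
    return (template_dna_ng / total_dna_ng) * volume_filtered_liters


def spike_dispersion(asv: AsvTable) -> pd.DataFrame:
    """QC statistic: per-sample dispersion across individual spike ASVs.

    With several synthetic spike sequences pooled into one normalization,
    their mutual spread flags samples where the spike behaved unevenly.
    Returns total spike reads, CV across spike ASVs and n spike ASVs.
    """
    spikes = asv.counts[list(asv.spike_asv_ids)].astype(float)
    total = spikes.sum(axis=1)
    if spikes.shape[1] >= 2:
        mean = spikes.mean(axis=1)
        sd = spikes.std(axis=1, ddof=1)
        cv = sd.div(mean.where(mean > 0, np.nan))
    else:
        cv = pd.Series(np.nan, index=spikes.index)
    return pd.DataFrame({"spike_reads": total, "spike_cv": cv,
                         "n_spike_asvs": spikes.shape[1]})


_CURRENCY_BY_COLUMN = {
    "cells_per_liter": "cells_per_liter",
    "biovolume_um3_per_liter": "biovolume",
    "carbon_ugC_per_liter": "carbon",
}


def microscopy_matrix(table: pd.DataFrame, value_col: str, rank: str) -> AbundanceMatrix:
    """Pivot a long microscopy table to a samples x taxa matrix at ``rank``.

    Records unassigned at the rank are pooled into an ``unassigned``
    column (dropped later by community restriction).
    """
    if rank not in RANKS:
        raise KeyError(f"unknown rank {rank!r}")
    if rank not in table.columns:
        raise ValidationError(f"microscopy table lacks rank column {rank!r}")
    wide = table.pivot_table(index="sample_id", columns=rank, values=value_col,
                             aggfunc="sum", fill_value=0.0)
    wide.columns.name = rank
    currency = _CURRENCY_BY_COLUMN.get(value_col, "cells_per_liter")
    return AbundanceMatrix(wide.astype(float), currency, rank=rank)


def to_long(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Tidy long form (sample, taxon, currency, value) of a matrix."""
    long = matrix.data.stack().rename("value").reset_index()
    long.columns = ["sample_id", "taxon", "value"]
    long.insert(2, "currency", matrix.currency)
    return long
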