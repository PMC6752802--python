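"""Per-site frequency tables and population statistics.

Aggregates per-specimen marker calls into per-location counts and
computes three statistics:

* COI strain frequencies — corn-strain frequency is
  ``(h1+h2+h3+h4)/n`` over specimens with a classified COIB segment
  (mitochondrial, one copy per specimen, so specimen counts are the
  denominator);
* the h2/h4 contrast ``(h4-h2)/(h2+h4)`` that separates the
  Western-Hemisphere TX-type and FL-type population groups;
* the Z-linked Tpi chromosome estimator.  Unsexed larvae carry two Z
  chromosomes if male and one if female, i.e. 1.5 Tpi copies per
  specimen on average under a 1:1 sex ratio.  Homozygous/hemizygous
  classes are therefore weighted 1.5 per specimen and heterozygotes
  contribute one chromosome of each allele:
  ``est_C = 1.5*TpiC + TpiH`` and ``est_R = 1.5*TpiR + TpiH``.
  Tpi allele frequencies are always reported on estimated chromosomes,
  never raw specimen counts, which would double-count heterozygotes.

The 1:1 sex-ratio assumption is exposed as ``male_fraction``: with
male fraction m the per-specimen copy multiplier is ``1 + m`` (2m from
males + (1-m) from females), reducing to 1.5 at m = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .markers import COI_CLASSES, TPI_CLASSES, MarkerCall

__all__ = [
    "SiteCountTable",
    "TxFlResult",
    "TpiChromosomeEstimate",
    "tally_calls",
    "strain_frequencies",
    "txfl_metric",
    "estimate_tpi_chromosomes",
    "summarize_dataset",
]


@dataclass
class SiteCountTable:
    """Per-site counts of COI and Tpi classes.

    ``df`` has one row per site_id with integer columns
    RS, h1..h4, coi_unclassified, TpiC, TpiR, TpiH, tpi_unclassified,
    n_coi, n_tpi.  Classified sample sizes: n_coi = RS+h1+h2+h3+h4 and
    n_tpi = TpiC+TpiR+TpiH; unclassified specimens are tracked in their
    own columns and excluded from all denominators.
    """

    df: pd.DataFrame

    COLUMNS = [
        "RS", "h1", "h2", "h3", "h4", "coi_unclassified",
        "TpiC", "TpiR", "TpiH", "tpi_unclassified",
        "n_coi", "n_tpi",
    ]

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing count columns: {missing}")
        if (self.df[self.COLUMNS] < 0).any().any():
            raise ValueError("negative counts")
        bad_coi = self.df["n_coi"] != self.df[list(COI_CLASSES)].sum(axis=1)
        bad_tpi = self.df["n_tpi"] != self.df[list(TPI_CLASSES)].sum(axis=1)
        if bad_coi.any() or bad_tpi.any():
            raise ValueError("sample sizes inconsistent with class counts")

    @property
    def sites(self) -> list[str]:
        return list(self.df.index)

    def counts(self, site: str) -> pd.Series:
        return self.df.loc[site]


def tally_calls(calls: Sequence[MarkerCall], sites: Iterable[str] | None = None) -> SiteCountTable:
    """Tally marker calls into a per-site count table.

    Every call is counted exactly once per locus: into its class if
    classified, into the unclassified column if the segment was located
    but uncallable, and not at all if the segment was never located
    (``no_segment``) — per-locus sample sizes therefore differ when
    amplification failed at one locus.  ``sites``, when given, must
    cover every site_id appearing in the calls (unknown site -> error)
    and fixes the row set; otherwise rows are the observed site_ids.
    Rows are ordered lexicographically.
    """
    known = set(sites) if sites is not None else None
    rows: dict[str, dict[str, int]] = {}
    for c in calls:
        if known is not None and c.site_id not in known:
            raise ValueError(f"call for unknown site {c.site_id!r}")
        row = rows.setdefault(
            c.site_id, {col: 0 for col in SiteCountTable.COLUMNS}
        )
        if c.coi is not None:
            if c.coi.coi_class in COI_CLASSES:
                row[c.coi.coi_class] += 1
                row["n_coi"] += 1
            else:
                row["coi_unclassified"] += 1
        if c.tpi is not None:
            if c.tpi.tpi_class in TPI_CLASSES:
                row[c.tpi.tpi_class] += 1
                row["n_tpi"] += 1
            else:
                row["tpi_unclassified"] += 1
    index = sorted(known) if known is not None else sorted(rows)
    df = pd.DataFrame(
        [rows.get(s, {col: 0 for col in SiteCountTable.COLUMNS}) for s in index],
        index=pd.Index(index, name="site_id"),
        columns=SiteCountTable.COLUMNS,
        dtype=int,
    )
    return SiteCountTable(df)


@dataclass
class TxFlResult:
    metric: float | None  #: (h4-h2)/(h2+h4); None when h2+h4 = 0
    h2_count: int
    h4_count: int
    label: str  #: "TX-type" / "FL-type" / "indeterminate"


def txfl_metric(
    h2_count: int, h4_count: int, threshold: float | None = None
) -> TxFlResult:
    """The h2/h4 contrast ``(h4-h2)/(h2+h4)`` in [-1, 1].

    Indeterminate when h2+h4 = 0.  Group labelling needs a reference
    cutoff that is configuration, not a constant: when ``threshold`` is
    given, metric >= threshold labels TX-type and metric < threshold
    FL-type; otherwise only the raw metric is reported.
    """
    if h2_count < 0 or h4_count < 0:
        raise ValueError("counts must be non-negative")
    if h2_count + h4_count == 0:
        return TxFlResult(None, h2_count, h4_count, "indeterminate")
    metric = (h4_count - h2_count) / (h2_count + h4_count)
    label = "indeterminate"
    if threshold is not None:
        label = "TX-type" if metric >= threshold else "FL-type"
    return TxFlResult(metric, h2_count, h4_count, label)


@dataclass
class TpiChromosomeEstimate:
    est_C: float
    est_R: float
    sex_ratio_assumption: float  #: assumed male fraction

    @property
    def total(self) -> float:
        return self.est_C + self.est_R

    @property
    def freq_C(self) -> float | None:
        return self.est_C / self.total if self.total > 0 else None


def estimate_tpi_chromosomes(
    n_tpi_c: int, n_tpi_r: int, n_tpi_h: int, male_fraction: float = 0.5
) -> TpiChromosomeEstimate:
    """Estimate Tpi-bearing chromosome counts from genotype classes.

    With male fraction m the average Z copies per specimen is
    ``2m + (1-m) = 1 + m``; homozygous/hemizygous classes are scaled by
    that multiplier and each heterozygote contributes one chromosome of
    each allele.  The default m = 0.5 gives the 1.5 rule.
    """
    if min(n_tpi_c, n_tpi_r, n_tpi_h) < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 <= male_fraction <= 1.0:
        raise ValueError("male_fraction must be in [0, 1]")
    mult = 1.0 + male_fraction
    return TpiChromosomeEstimate(
        est_C=mult * n_tpi_c + n_tpi_h,
        est_R=mult * n_tpi_r + n_tpi_h,
        sex_ratio_assumption=male_fraction,
    )


def strain_frequencies(
    table: SiteCountTable, site: str, male_fraction: float = 0.5
) -> dict[str, float | None]:
    """COI strain frequencies (per specimen) and the Tpi corn-strain
    allele frequency (per estimated chromosome) for one site.  Zero
    denominators yield ``None`` (undefined), never 0."""
    row = table.counts(site)
    n_coi = int(row["n_coi"])
    cs = int(row[["h1", "h2", "h3", "h4"]].sum())
    est = estimate_tpi_chromosomes(
        int(row["TpiC"]), int(row["TpiR"]), int(row["TpiH"]), male_fraction
    )
    return {
        "freq_coi_cs": cs / n_coi if n_coi else None,
        "freq_coi_rs": int(row["RS"]) / n_coi if n_coi else None,
        "freq_tpi_c": est.freq_C,
    }


def summarize_dataset(
    table: SiteCountTable,
    male_fraction: float = 0.5,
    txfl_threshold: float | None = None,
) -> pd.DataFrame:
    """One row per site (lexicographic order) with sample sizes,
    frequencies, the h2/h4 contrast and the chromosome estimates."""
    rows = []
    for site in table.sites:
        row = table.counts(site)
        freqs = strain_frequencies(table, site, male_fraction)
        est = estimate_tpi_chromosomes(
            int(row["TpiC"]), int(row["TpiR"]), int(row["TpiH"]), male_fraction
        )
        tx = txfl_metric(int(row["h2"]), int(row["h4"]), txfl_threshold)
        rows.append(
            {
                "site_id": site,
                "n_coi": int(row["n_coi"]),
                "n_tpi": int(row["n_tpi"]),
                "coi_unclassified": int(row["coi_unclassified"]),
                "tpi_unclassified": int(row["tpi_unclassified"]),
                "freq_coi_cs": freqs["freq_coi_cs"],
                "freq_coi_rs": freqs["freq_coi_rs"],
                "est_tpi_c_chromosomes": est.est_C,
                "est_tpi_r_chromosomes": est.est_R,
                "freq_tpi_c": freqs["freq_tpi_c"],
                "txfl_metric": tx.metric,
                "txfl_label": tx.label,
            }
        )
    cols = [
        "site_id", "n_coi", "n_tpi", "coi_unclassified", "tpi_unclassified",
        "freq_coi_cs", "freq_coi_rs",
        "est_tpi_c_chromosomes", "est_tpi_r_chromosomes", "freq_tpi_c",
        "txfl_metric", "txfl_label",
    ]
    return pd.DataFrame(rows, columns=cols).set_index("site_id")


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    """Export the per-site summary with frequencies at 4 decimals."""
    out = summary.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(
                lambda v: f"{v:.4f}" if pd.notna(v) else ""
            )
    out.to_csv(path)
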