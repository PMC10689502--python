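"""Absolute protein quantification from SIP metaproteomics tables.

Implements the "total protein approach" chain that turns label-free
quantification (LFQ) intensities into absolute protein concentrations, and
combines them with peptide-labeling metrics to estimate how much newly made
(13C-labeled) protein each metagenome-assembled genome (MAG) accumulated
during a stable-isotope-probing incubation:

1. relative abundance of protein i in a sample: its LFQ intensity divided by
   the summed intensity of all proteins in that sample (g/g);
2. absolute mass concentration: relative abundance times the bulk protein
   concentration of the sample (g/L);
3. molar concentration: mass concentration divided by molecular weight,
   scaled to nmol/L;
4. per-MAG 13C-protein: the MAG's summed protein mass (mg/L) times the
   unweighted mean relative isotope abundance (RIA, the 13C atom fraction of
   labeled peptides) times the unweighted mean labeling ratio (LR, the
   labeled fraction of the peptide signal) over that MAG's labeled proteins.

A community biomass yield follows from the summed 13C-protein at the end of
the incubation, a protein-to-biomass ratio (g protein per g volatile
suspended solids, VSS), and the acetate dose.

All tabular inputs/outputs are tidy pandas DataFrames; TSV readers live at
the bottom of the module.  RIA and LR are held internally as fractions in
[0, 1]; readers accept percent-scaled columns and convert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampleContext",
    "relative_protein_abundance",
    "total_protein_g_per_l",
    "total_protein_nmol_per_l",
    "mag_c13_protein",
    "metaproteome_fraction",
    "biomass_yield",
    "quantify_sample",
    "quantify_all_samples",
    "read_proteins",
    "read_lfq",
    "read_labels",
    "read_samples",
]

#: default acetate COD factor, g-COD per g acetate ion (CH3COO-, MW 59;
#: 2 mol O2 = 64 g per mol acetate oxidized)
ACETATE_COD_FACTOR = 64.0 / 59.0


@dataclass(frozen=True)
class SampleContext:
    """Per-sample metadata: time point, replicate, bulk protein concentration."""

    sample_id: str
    time_h: float
    replicate: int
    total_protein_conc: float  # g/L

    def __post_init__(self) -> None:
        if self.total_protein_conc < 0:
            raise ValueError(
                f"total protein concentration must be >= 0 "
                f"(sample {self.sample_id}: {self.total_protein_conc})"
            )
        if self.time_h < 0:
            raise ValueError(f"time must be >= 0 (sample {self.sample_id})")


def _sample_slice(lfq: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    sub = lfq[lfq["sample_id"] == sample_id]
    if sub.empty:
        raise KeyError(f"sample {sample_id!r} not present in LFQ table")
    if sub["protein_id"].duplicated().any():
        dups = sub.loc[sub["protein_id"].duplicated(), "protein_id"].unique()
        raise ValueError(
            f"duplicate LFQ rows for sample {sample_id!r}: {list(dups[:5])}"
        )
    if (sub["lfq_intensity"] < 0).any():
        raise ValueError(f"negative LFQ intensity in sample {sample_id!r}")
    return sub


def relative_protein_abundance(lfq: pd.DataFrame, sample_id: str) -> pd.Series:
    """Relative protein abundance (g/g) of every protein in one sample.

    Returns a Series indexed by protein_id summing to 1.  Raises if the
    sample's intensities are all zero (the normalization is undefined).
    """
    sub = _sample_slice(lfq, sample_id)
    total = sub["lfq_intensity"].sum()
    if total <= 0:
        raise ValueError(
            f"sample {sample_id!r} has zero total LFQ intensity; "
            "relative abundance is undefined"
        )
    rel = sub.set_index("protein_id")["lfq_intensity"] / total
    rel.name = "relative_abundance"
    return rel


def total_protein_g_per_l(rel_abund: pd.Series, context: SampleContext) -> pd.Series:
    """Absolute protein concentration (g/L): relative abundance x bulk protein."""
    out = rel_abund * context.total_protein_conc
    out.name = "total_protein_g_per_l"
    return out


def total_protein_nmol_per_l(
    total_g_per_l: pd.Series, proteins: pd.DataFrame
) -> pd.Series:
    """Molar protein concentration (nmol/L) using per-protein molecular weights."""
    mw = proteins.set_index("protein_id")["molecular_weight"]
    missing = total_g_per_l.index.difference(mw.index)
    if len(missing) > 0:
        raise KeyError(
            f"no molecular weight for protein(s): {list(missing[:5])}"
        )
    mw = mw.reindex(total_g_per_l.index)
    if (mw <= 0).any():
        bad = mw.index[mw <= 0][0]
        raise ValueError(f"non-positive molecular weight for protein {bad!r}")
    out = total_g_per_l / mw * 1e9
    out.name = "total_protein_nmol_per_l"
    return out


def _check_fraction(values: pd.Series, name: str) -> None:
    if ((values < 0) | (values > 1)).any():
        raise ValueError(
            f"{name} outside [0, 1]; values must be fractions, not percent "
            f"(max seen: {values.max():g})"
        )


def mag_c13_protein(
    total_g_per_l: pd.Series,
    labels: pd.DataFrame,
    proteins: pd.DataFrame,
    sample_id: str,
) -> pd.DataFrame:
    """Per-MAG 13C-protein concentration for one sample.

    For each MAG: (sum of its proteins' total protein, mg/L) x (mean RIA over
    its labeled proteins in the sample) x (mean LR likewise).  Means are
    unweighted; proteins quantified by LFQ but without a label row contribute
    to the MAG's total protein but not to the means; MAGs with no labeled
    protein get c13_protein = 0.

    Returns a DataFrame indexed by mag_id with columns
    ``total_protein_mg_per_l, mean_ria, mean_lr, n_labeled, c13_protein_mg_per_l``.
    """
    mag_of = proteins.set_index("protein_id")["mag_id"]
    missing = total_g_per_l.index.difference(mag_of.index)
    if len(missing) > 0:
        raise KeyError(f"protein(s) without MAG assignment: {list(missing[:5])}")

    mg_per_l = total_g_per_l * 1e3
    totals = mg_per_l.groupby(mag_of.reindex(mg_per_l.index)).sum()

    lab = labels[labels["sample_id"] == sample_id].copy()
    _check_fraction(lab["ria"], "RIA")
    _check_fraction(lab["lr"], "LR")
    # label rows for proteins we cannot place in a MAG are dropped
    lab = lab[lab["protein_id"].isin(mag_of.index)]
    lab["mag_id"] = mag_of.reindex(lab["protein_id"]).to_numpy()
    means = lab.groupby("mag_id").agg(
        mean_ria=("ria", "mean"), mean_lr=("lr", "mean"), n_labeled=("ria", "size")
    )

    out = pd.DataFrame({"total_protein_mg_per_l": totals})
    out = out.join(means)
    out["mean_ria"] = out["mean_ria"].fillna(0.0)
    out["mean_lr"] = out["mean_lr"].fillna(0.0)
    out["n_labeled"] = out["n_labeled"].fillna(0).astype(int)
    out["c13_protein_mg_per_l"] = (
        out["total_protein_mg_per_l"] * out["mean_ria"] * out["mean_lr"]
    )
    out.index.name = "mag_id"
    return out


def metaproteome_fraction(rel_abund: pd.Series, proteins: pd.DataFrame) -> pd.Series:
    """Fraction of the metaproteome attributable to each MAG (sums to 1)."""
    mag_of = proteins.set_index("protein_id")["mag_id"]
    missing = rel_abund.index.difference(mag_of.index)
    if len(missing) > 0:
        raise KeyError(f"protein(s) without MAG assignment: {list(missing[:5])}")
    out = rel_abund.groupby(mag_of.reindex(rel_abund.index)).sum()
    out.name = "metaproteome_fraction"
    return out


def biomass_yield(
    c13_protein_mg_per_l: float,
    acetate_dose_mg_per_l: float,
    protein_per_vss: float = 0.5,
    cod_per_vss: float = 1.42,
    cod_per_g_acetate: float = ACETATE_COD_FACTOR,
) -> tuple[float, float]:
    """Community biomass yield from total 13C-protein at the end of labeling.

    Parameters use the conventional anaerobic-digestion currencies: a
    protein-to-biomass ratio of 0.5 g protein per g VSS and a biomass COD
    equivalent of 1.42 g COD per g VSS.

    Returns ``(g-VSS per g-acetate, g-COD_biomass per g-COD_acetate)``.
    """
    if acetate_dose_mg_per_l <= 0:
        raise ValueError("acetate dose must be positive")
    if c13_protein_mg_per_l < 0:
        raise ValueError("13C-protein concentration must be >= 0")
    vss = c13_protein_mg_per_l / protein_per_vss
    y_vss = vss / acetate_dose_mg_per_l
    y_cod = y_vss * cod_per_vss / cod_per_g_acetate
    return y_vss, y_cod


def quantify_sample(
    proteins: pd.DataFrame,
    lfq: pd.DataFrame,
    labels: pd.DataFrame,
    context: SampleContext,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full quantification chain for one sample.

    Returns ``(per_protein, per_mag)``: per-protein absolute quantities and
    the per-MAG label summary.
    """
    rel = relative_protein_abundance(lfq, context.sample_id)
    gpl = total_protein_g_per_l(rel, context)
    nmol = total_protein_nmol_per_l(gpl, proteins)
    per_protein = pd.DataFrame(
        {
            "relative_abundance": rel,
            "total_protein_g_per_l": gpl,
            "total_protein_nmol_per_l": nmol,
        }
    )
    per_protein.index.name = "protein_id"
    per_mag = mag_c13_protein(gpl, labels, proteins, context.sample_id)
    per_mag.insert(0, "sample_id", context.sample_id)
    per_mag.insert(1, "time_h", context.time_h)
    frac = metaproteome_fraction(rel, proteins)
    per_mag["metaproteome_fraction"] = frac.reindex(per_mag.index).fillna(0.0)
    return per_protein, per_mag


def quantify_all_samples(
    proteins: pd.DataFrame,
    lfq: pd.DataFrame,
    labels: pd.DataFrame,
    samples: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify every sample in the samples table; concatenated tidy outputs."""
    per_protein_all, per_mag_all = [], []
    for row in samples.itertuples(index=False):
        ctx = SampleContext(
            sample_id=row.sample_id,
            time_h=float(row.time_h),
            replicate=int(row.replicate),
            total_protein_conc=float(row.total_protein_g_per_l),
        )
        pp, pm = quantify_sample(proteins, lfq, labels, ctx)
        pp = pp.reset_index()
        pp.insert(0, "sample_id", ctx.sample_id)
        per_protein_all.append(pp)
        per_mag_all.append(pm.reset_index())
    return (
        pd.concat(per_protein_all, ignore_index=True),
        pd.concat(per_mag_all, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# TSV readers (UTF-8, header row, '#' comments)
# ---------------------------------------------------------------------------

def _read_tsv(path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def read_proteins(path) -> pd.DataFrame:
    """Read proteins.tsv (protein_id, mag_id, molecular_weight).

    Proteins listed under more than one MAG are ambiguous and excluded
    (counted in the log), since the per-MAG aggregation relies on unique
    assignments.
    """
    df = _read_tsv(path, {"protein_id", "mag_id", "molecular_weight"})
    n_mags = df.groupby("protein_id")["mag_id"].nunique()
    ambiguous = n_mags.index[n_mags > 1]
    if len(ambiguous) > 0:
        logger.warning(
            "excluding %d protein(s) assigned to multiple MAGs", len(ambiguous)
        )
        df = df[~df["protein_id"].isin(ambiguous)]
    df = df.drop_duplicates("protein_id")
    if (df["molecular_weight"] <= 0).any():
        raise ValueError(f"{path}: molecular weights must be positive")
    return df.reset_index(drop=True)


def read_lfq(path) -> pd.DataFrame:
    """Read lfq.tsv (sample_id, protein_id, lfq_intensity)."""
    df = _read_tsv(path, {"sample_id", "protein_id", "lfq_intensity"})
    if (df["lfq_intensity"] < 0).any():
        raise ValueError(f"{path}: LFQ intensities must be >= 0")
    return df


def read_labels(path, unit: str | None = None) -> pd.DataFrame:
    """Read labels.tsv (sample_id, protein_id, ria, lr[, unit]).

    ``unit`` is 'percent' or 'fraction'; if None it is taken from a ``unit``
    column (MetaProSIP emits RIA as a percentage) or defaults to 'fraction'.
    Values are returned as fractions.
    """
    df = _read_tsv(path, {"sample_id", "protein_id", "ria", "lr"})
    if unit is None:
        unit = str(df["unit"].iloc[0]) if "unit" in df.columns else "fraction"
    if unit not in ("percent", "fraction"):
        raise ValueError(f"unit must be 'percent' or 'fraction', got {unit!r}")
    if unit == "percent":
        df = df.assign(ria=df["ria"] / 100.0, lr=df["lr"] / 100.0)
    for col in ("ria", "lr"):
        _check_fraction(df[col], col.upper())
    return df.drop(columns=[c for c in ("unit",) if c in df.columns])


def read_samples(path) -> pd.DataFrame:
    """Read samples.tsv (sample_id, time_h, replicate, total_protein_g_per_l)."""
    df = _read_tsv(
        path, {"sample_id", "time_h", "replicate", "total_protein_g_per_l"}
    )
    if (df["total_protein_g_per_l"] < 0).any():
        raise ValueError(f"{path}: total protein concentrations must be >= 0")
    return df
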