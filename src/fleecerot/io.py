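"""Tabular readers/writers and probe-level editing rules.

All tables are tab-separated with a header, one record per row.  The probe
table is long format — one row per (probe, array, dye channel) reading —
with foreground, background and signal-to-noise columns; GenePix-style
exports can be adapted with a column map.  Editing rules:

* a probe is *undetectable*, and removed, iff its signal-to-noise ratio is
  below one in every hybridisation and channel;
* a gene represented by several probes keeps only its most abundant probe
  (highest mean background-corrected intensity across all hybridisations);
* readings are background-corrected by subtraction and log2-transformed;
  readings with foreground <= background are dropped and counted rather
  than floored.

Anonymous probes (no gene annotation) pass through with the probe id
standing in as the gene id.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROBE_COLUMNS = ["probe_id", "gene_id", "array_id", "block_id", "dye",
                 "foreground", "background", "snr"]

OBS_COLUMNS = ["array_id", "block_id", "dye", "gene_id", "flock_id",
               "treatment_id", "log2_intensity"]


class DesignError(ValueError):
    pass


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def read_probe_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a long-format probe reading table.

    ``column_map`` renames source columns (e.g. GenePix export names such as
    ``{"F532 Median": "foreground", ...}``) onto the canonical schema.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in PROBE_COLUMNS if c not in df.columns and c != "gene_id"]
    if missing:
        raise DesignError(f"probe table lacks columns: {missing}")
    if "gene_id" not in df.columns:
        df["gene_id"] = pd.NA
    if (df["foreground"] < 0).any() or (df["snr"] < 0).any():
        raise DesignError("foreground and snr must be non-negative")
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    """(array_id, dye) -> (flock_id, treatment_id) sample map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"array_id", "dye", "flock_id", "treatment_id"}
    if not need <= set(df.columns):
        raise DesignError(f"sample sheet lacks columns: {sorted(need - set(df.columns))}")
    if df.duplicated(["array_id", "dye"]).any():
        raise DesignError("sample sheet has duplicate (array_id, dye) entries")
    return df


def read_pedigree(path) -> pd.DataFrame:
    """Pedigree TSV (animal_id, sire_id, dam_id); 0/NA marks unknown parents."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
    need = {"animal_id", "sire_id", "dam_id"}
    if not need <= set(df.columns):
        raise DesignError(f"pedigree lacks columns: {sorted(need - set(df.columns))}")
    return df


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["animal_id"] = df["animal_id"].astype(str)
    return df


def read_genotypes(path) -> pd.DataFrame:
    """Genotype TSV: one row per animal, one column per SNP.

    Calls may be allele pairs like ``A/G`` or numeric dosages 0/1/2;
    missing is NA, ``.`` or ``./.``.  Allele-pair columns are converted to
    minor-allele dosage.  Monomorphic columns are allowed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "animal_id" not in df.columns:
        raise DesignError("genotype table needs an animal_id column")
    out = pd.DataFrame({"animal_id": df["animal_id"].astype(str)})
    for col in df.columns:
        if col == "animal_id":
            continue
        out[col] = _to_dosage(df[col])
    return out


def _to_dosage(calls: pd.Series) -> pd.Series:
    vals = calls.astype("string").str.strip()
    vals = vals.where(~vals.isin([".", "./.", "NA", ""]), pd.NA)
    if vals.dropna().str.fullmatch(r"[0-2]").all():
        return pd.to_numeric(vals, errors="raise").astype("Float64")
    pairs = vals.dropna().str.split("/", expand=True)
    if pairs.shape[1] != 2:
        raise DesignError(f"cannot parse genotype calls in column {calls.name!r}")
    alleles = pd.concat([pairs[0], pairs[1]])
    counts = alleles.value_counts()
    if len(counts) > 2:
        raise DesignError(f"SNP {calls.name!r} has more than two alleles")
    minor = counts.index[-1] if len(counts) == 2 else counts.index[0]
    dosage = (pairs[0] == minor).astype(int) + (pairs[1] == minor).astype(int)
    out = pd.Series(pd.NA, index=vals.index, dtype="Float64")
    out.loc[dosage.index] = dosage.astype(float)
    return out


def read_annotation(path) -> pd.DataFrame:
    """Flat gene -> term annotation TSV (gene_id, term_id[, term_name])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene_id", "term_id"}
    if not need <= set(df.columns):
        raise DesignError(f"annotation lacks columns: {sorted(need - set(df.columns))}")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return df


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in OBS_COLUMNS[:-1]})
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise DesignError(f"observation table lacks columns: {missing}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Canonical writer: TSV, no index. Tables round-trip bit-identically."""
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# probe editing
# --------------------------------------------------------------------------

def filter_undetectable(probes: pd.DataFrame) -> pd.DataFrame:
    """Drop probes whose SNR is < 1 in *every* hybridisation and channel."""
    if probes.empty:
        warnings.warn("empty probe table", stacklevel=2)
        return probes.copy()
    keep = probes.groupby("probe_id")["snr"].transform("max") >= 1.0
    out = probes.loc[keep].copy()
    logger.info("SNR filter: %d of %d probes retained",
                out["probe_id"].nunique(), probes["probe_id"].nunique())
    return out


def collapse_probes_to_genes(probes: pd.DataFrame) -> pd.DataFrame:
    """Keep, per annotated gene, the most abundant probe.

    Abundance is the mean background-corrected intensity across all
    hybridisations and channels; ties break to the lexicographically
    smallest probe id.  Anonymous probes (missing gene_id) become their own
    gene.
    """
    probes = probes.copy()
    anon = probes["gene_id"].isna() | (probes["gene_id"].astype(str).str.len() == 0)
    probes.loc[anon, "gene_id"] = probes.loc[anon, "probe_id"]
    net = probes["foreground"] - probes["background"]
    means = (pd.DataFrame({"gene_id": probes["gene_id"], "probe_id": probes["probe_id"],
                           "net": net})
             .groupby(["gene_id", "probe_id"], as_index=False)["net"].mean()
             .sort_values(["gene_id", "net", "probe_id"],
                          ascending=[True, False, True], kind="mergesort"))
    winners = means.drop_duplicates("gene_id")["probe_id"]
    out = probes[probes["probe_id"].isin(set(winners))].copy()
    logger.info("probe collapse: %d probes -> %d genes",
                probes["probe_id"].nunique(), out["gene_id"].nunique())
    return out


def to_observations(probes: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Background-correct, log2-transform and attach sample metadata.

    ``design`` maps every (array_id, dye) to its (flock_id, treatment_id).
    Readings with foreground <= background are dropped; the count is stored
    in ``result.attrs['n_dropped_nonpositive']`` and logged.
    """
    pairs = set(map(tuple, design[["array_id", "dye"]].itertuples(index=False)))
    present = set(map(tuple, probes[["array_id", "dye"]].drop_duplicates()
                      .itertuples(index=False)))
    orphan = present - pairs
    if orphan:
        raise DesignError(f"(array, dye) pairs missing from the sample sheet: "
                          f"{sorted(orphan)[:5]}")
    net = probes["foreground"] - probes["background"]
    ok = net > 0
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d readings with foreground <= background", n_dropped)
    kept = probes.loc[ok].copy()
    kept["log2_intensity"] = np.log2(net[ok])
    obs = kept.merge(design, on=["array_id", "dye"], how="left", validate="m:1")
    obs = obs[OBS_COLUMNS].reset_index(drop=True)
    obs.attrs["n_dropped_nonpositive"] = n_dropped
    return obs
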