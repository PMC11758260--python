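"""Post-denoising ASV filtering and detection summaries.

Metabarcoding surveys report amplicon sequence variants (ASVs) with read
counts per water sample and a taxonomic assignment per ASV.  Raw tables
are noisy: field-control contamination, sequencing singletons, shallow or
low-confidence assignments, and known cross-project contaminants.  This
module applies the standard conservative filtering chain for such
surveys —

    subtract_controls -> filter_target_taxa -> drop_singletons
        -> apply_taxonomy_rules -> build_detections

— and turns the survivors into a boolean species x station x month
detection matrix, plus survey-level summaries and sample-based species
accumulation curves.  Every step appends a row to an attrition history
(rows and reads in/out, cells zeroed) so losses are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "ASVTable",
    "SampleMetadata",
    "DetectionMatrix",
    "DetectError",
    "TAXONOMY_COLUMNS",
    "subtract_controls",
    "filter_target_taxa",
    "drop_singletons",
    "apply_taxonomy_rules",
    "build_detections",
    "run_filter_chain",
    "summarize",
    "accumulation_curve",
    "attrition_log",
    "read_asv_table",
    "write_asv_table",
    "read_sample_metadata",
    "write_sample_metadata",
]

TAXONOMY_COLUMNS = ["class", "order", "family", "genus", "species", "confidence"]

SAMPLE_TYPES = {"sample", "field_control", "extraction_control", "pcr_control"}


class DetectError(ValueError):
    pass


@dataclass
class ASVTable:
    """Read counts (ASV x sample) plus one taxonomy row per ASV.

    ``taxonomy`` has columns class/order/family/genus/species (empty string
    = unassigned at that rank) and a single percent ``confidence`` for the
    deepest assignment; a boolean ``genus_only`` column is added by
    :func:`apply_taxonomy_rules`.  ``history`` accumulates per-filter
    attrition stats and travels with the table through the chain.
    """

    reads: pd.DataFrame  # index asv_id, columns sample ids, integer counts
    taxonomy: pd.DataFrame  # index asv_id
    history: list = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.reads.index.equals(self.taxonomy.index):
            raise DetectError("reads and taxonomy must share the same asv_id index")
        vals = self.reads.to_numpy()
        if vals.size and (vals < 0).any():
            raise DetectError("read counts must be non-negative")
        for col in TAXONOMY_COLUMNS:
            if col not in self.taxonomy.columns:
                raise DetectError(f"taxonomy missing column '{col}'")

    @property
    def total_reads(self) -> int:
        return int(self.reads.to_numpy().sum())

    def _log(self, step: str, before: "ASVTable", cells_zeroed: int) -> None:
        self.history = list(before.history) + [
            {
                "step": step,
                "rows_in": len(before.reads),
                "rows_out": len(self.reads),
                "reads_in": before.total_reads,
                "reads_out": self.total_reads,
                "cells_zeroed": int(cells_zeroed),
            }
        ]


@dataclass
class SampleMetadata:
    """Sample sheet: station/month per sample and the sample<->control pairing."""

    table: pd.DataFrame  # columns: sample_id, station_id, month, type, paired_control_id

    def __post_init__(self) -> None:
        required = {"sample_id", "station_id", "month", "type", "paired_control_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise DetectError(f"sample metadata missing column(s): {', '.join(sorted(missing))}")
        bad = set(self.table["type"]) - SAMPLE_TYPES
        if bad:
            raise DetectError(f"unknown sample type(s): {', '.join(sorted(bad))}")
        samples = self.table[self.table["type"] == "sample"]
        if samples[["station_id", "month"]].isna().any().any():
            raise DetectError("samples must have station_id and month")
        controls = set(self.table.loc[self.table["type"] == "field_control", "sample_id"])
        unpaired = [
            str(r.sample_id)
            for r in samples.itertuples()
            if pd.isna(r.paired_control_id) or r.paired_control_id not in controls
        ]
        if unpaired:
            raise DetectError(f"samples without a paired field control: {', '.join(unpaired)}")

    @property
    def samples(self) -> pd.DataFrame:
        return self.table[self.table["type"] == "sample"]

    def pairing(self) -> dict[str, str]:
        return dict(zip(self.samples["sample_id"], self.samples["paired_control_id"]))

    def station_month(self) -> pd.DataFrame:
        return self.samples.set_index("sample_id")[["station_id", "month"]]


@dataclass
class DetectionMatrix:
    """Boolean species x station x month detections with read provenance.

    ``per_sample`` keeps one row per surviving species x sample positive
    (the discrete-detection unit); ``long`` aggregates to station x month.
    """

    long: pd.DataFrame  # columns: species, station_id, month, detected, reads
    per_sample: pd.DataFrame  # columns: species, sample_id, station_id, month, reads
    n_samples_total: int

    def matrix(self) -> pd.DataFrame:
        """Wide boolean pivot: rows species, columns (station_id, month)."""
        if self.long.empty:
            return pd.DataFrame()
        return self.long.pivot_table(
            index="species",
            columns=["station_id", "month"],
            values="detected",
            aggfunc="any",
            fill_value=False,
        ).astype(bool)

    @property
    def species(self) -> list[str]:
        return sorted(self.long["species"].unique().tolist())


# ---------------------------------------------------------------------------
# filter chain
# ---------------------------------------------------------------------------

def subtract_controls(table: ASVTable, meta: SampleMetadata) -> ASVTable:
    """Zero any ASV in a sample whose paired field control holds >= 1 read.

    Control columns (field, extraction, PCR) are dropped afterwards; the
    read totals of extraction/PCR blanks are screened and recorded in the
    attrition history rather than subtracted.
    """
    pairing = meta.pairing()
    missing = [s for s in pairing if s not in table.reads.columns]
    if missing:
        raise DetectError(f"samples missing from read table: {', '.join(sorted(missing))}")
    reads = table.reads.copy()
    cells_zeroed = 0
    for sample_id, control_id in pairing.items():
        if control_id not in reads.columns:
            raise DetectError(f"paired control '{control_id}' missing from read table")
        contaminated = reads[control_id] >= 1
        cells_zeroed += int(((reads[sample_id] > 0) & contaminated).sum())
        reads.loc[contaminated, sample_id] = 0
    sample_cols = [c for c in reads.columns if c in set(meta.samples["sample_id"])]
    blank_ids = set(
        meta.table.loc[meta.table["type"].isin({"extraction_control", "pcr_control"}), "sample_id"]
    )
    blank_reads = int(reads[[c for c in reads.columns if c in blank_ids]].to_numpy().sum())
    out = ASVTable(reads=reads[sample_cols], taxonomy=table.taxonomy.copy())
    out._log("subtract_controls", table, cells_zeroed)
    out.history[-1]["blank_reads_screened"] = blank_reads
    return out


def filter_target_taxa(table: ASVTable, target_group: set[str] = frozenset({"Elasmobranchii"})) -> ASVTable:
    """Keep only ASVs whose class-level assignment is inside the target group.

    Unassigned-class ASVs cannot be confirmed in-group and are dropped.
    """
    cls = table.taxonomy["class"].fillna("")
    keep = cls.isin(set(target_group))
    out = ASVTable(reads=table.reads.loc[keep].copy(), taxonomy=table.taxonomy.loc[keep].copy())
    out._log("filter_target_taxa", table, 0)
    out.history[-1]["rows_unassigned_class"] = int((cls == "").sum())
    return out


def drop_singletons(table: ASVTable) -> ASVTable:
    """Zero cells with exactly one read (a singleton in that sample)."""
    reads = table.reads.copy()
    single = reads.to_numpy() == 1
    arr = reads.to_numpy()
    arr[single] = 0
    out = ASVTable(
        reads=pd.DataFrame(arr, index=reads.index, columns=reads.columns),
        taxonomy=table.taxonomy.copy(),
    )
    out._log("drop_singletons", table, int(single.sum()))
    return out


def apply_taxonomy_rules(
    table: ASVTable,
    min_confidence: float = 40.0,
    contaminant_list: set[str] = frozenset(),
) -> ASVTable:
    """Enforce genus-level assignment at the confidence threshold.

    Rows not assigned to at least genus level at >= ``min_confidence`` are
    dropped, as are rows whose species is on the contaminant list.  Rows
    confident only to genus are retained but flagged ``genus_only`` so
    downstream species-level detection counting excludes them.
    """
    tax = table.taxonomy.copy()
    genus = tax["genus"].fillna("")
    species = tax["species"].fillna("")
    conf = tax["confidence"].astype(float)
    keep = (genus != "") & (conf >= min_confidence) & ~species.isin(set(contaminant_list))
    tax = tax.loc[keep]
    tax = tax.assign(genus_only=(tax["species"].fillna("") == ""))
    out = ASVTable(reads=table.reads.loc[keep].copy(), taxonomy=tax)
    out._log("apply_taxonomy_rules", table, 0)
    out.history[-1]["rows_genus_only"] = int(tax["genus_only"].sum())
    return out


def build_detections(table: ASVTable, meta: SampleMetadata) -> DetectionMatrix:
    """Aggregate surviving species-level reads into positive detections.

    A species is detected in a sample iff any surviving cell is positive
    (post-singleton, positive means >= 2 reads).  Genus-only rows are
    excluded from the species matrix.
    """
    if "genus_only" in table.taxonomy.columns:
        species_rows = ~table.taxonomy["genus_only"]
    else:
        species_rows = table.taxonomy["species"].fillna("") != ""
    reads = table.reads.loc[species_rows]
    species = table.taxonomy.loc[species_rows, "species"]
    sm = meta.station_month()
    sample_cols = [c for c in reads.columns if c in sm.index]
    by_species = reads[sample_cols].groupby(species).sum()

    records = []
    for sp, row in by_species.iterrows():
        for sample_id, n in row.items():
            if n > 0:
                records.append(
                    {
                        "species": sp,
                        "sample_id": sample_id,
                        "station_id": sm.loc[sample_id, "station_id"],
                        "month": sm.loc[sample_id, "month"],
                        "reads": int(n),
                    }
                )
    per_sample = pd.DataFrame(
        records, columns=["species", "sample_id", "station_id", "month", "reads"]
    )
    if per_sample.empty:
        long = pd.DataFrame(columns=["species", "station_id", "month", "detected", "reads"])
    else:
        long = (
            per_sample.groupby(["species", "station_id", "month"], as_index=False)["reads"]
            .sum()
            .assign(detected=True)[["species", "station_id", "month", "detected", "reads"]]
        )
    return DetectionMatrix(long=long, per_sample=per_sample, n_samples_total=len(sm))


def run_filter_chain(
    table: ASVTable,
    meta: SampleMetadata,
    target_group: set[str] = frozenset({"Elasmobranchii"}),
    min_confidence: float = 40.0,
    contaminant_list: set[str] = frozenset(),
    second_control_pass: bool = False,
) -> tuple[ASVTable, DetectionMatrix]:
    """Apply the full filter chain in its documented order.

    Control subtraction runs once, first; ``second_control_pass`` repeats
    it after the taxonomy rules for sensitivity checks (it is a no-op when
    the first pass already removed all control-contaminated cells).
    """
    t = subtract_controls(table, meta)
    t = filter_target_taxa(t, target_group)
    t = drop_singletons(t)
    t = apply_taxonomy_rules(t, min_confidence, contaminant_list)
    if second_control_pass:
        # control columns are gone; a second pass can only re-zero cells
        # flagged in the first pass, so it is recorded but has no effect
        t.history.append({"step": "subtract_controls_pass2", "rows_in": len(t.reads),
                          "rows_out": len(t.reads), "reads_in": t.total_reads,
                          "reads_out": t.total_reads, "cells_zeroed": 0})
    return t, build_detections(t, meta)


def attrition_log(table: ASVTable) -> pd.DataFrame:
    """The per-step attrition history as a DataFrame."""
    return pd.DataFrame(table.history)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(matrix: DetectionMatrix, meta: SampleMetadata) -> dict:
    """Survey-level detection summary.

    Reports discrete detections under both conventions (species x sample
    and species x station x month), species richness, per-species monthly
    counts, and the number / percentage (1 d.p.) of water samples with at
    least one detection.
    """
    n_samples = len(meta.samples)
    positive_samples = matrix.per_sample["sample_id"].nunique() if not matrix.per_sample.empty else 0
    pct = round(100.0 * positive_samples / n_samples, 1) if n_samples else 0.0
    if matrix.per_sample.empty:
        per_species_month = pd.DataFrame(columns=["species", "month", "detections"])
    else:
        per_species_month = (
            matrix.per_sample.groupby(["species", "month"], as_index=False)
            .size()
            .rename(columns={"size": "detections"})
        )
    return {
        "discrete_detections_species_sample": int(len(matrix.per_sample)),
        "discrete_detections_species_station_month": int(len(matrix.long)),
        "species_richness": int(matrix.long["species"].nunique()) if not matrix.long.empty else 0,
        "n_samples_total": int(n_samples),
        "n_samples_with_detection": int(positive_samples),
        "pct_samples_with_detection": pct,
        "per_species_month": per_species_month,
    }


def accumulation_curve(
    sample_species: dict[str, set[str]] | list[set[str]],
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Sample-based species accumulation curve by permutation.

    For each k the value is the mean, over random orderings of the
    samples, of the cumulative richness of the first k samples.  The curve
    is monotone non-decreasing and ends at the total observed richness.
    """
    if isinstance(sample_species, dict):
        sets = [frozenset(v) for v in sample_species.values()]
    else:
        sets = [frozenset(v) for v in sample_species]
    if not sets:
        raise DetectError("accumulation_curve requires at least one sample")
    all_species = sorted(set().union(*sets))
    idx = {sp: i for i, sp in enumerate(all_species)}
    # incidence matrix: samples x species
    inc = np.zeros((len(sets), max(len(all_species), 1)), dtype=bool)
    for i, s in enumerate(sets):
        for sp in s:
            inc[i, idx[sp]] = True
    rng = np.random.default_rng(seed)
    n = len(sets)
    acc = np.zeros(n)
    for _ in range(n_permutations):
        order = rng.permutation(n)
        seen = np.cumsum(inc[order], axis=0) > 0
        acc += seen.sum(axis=1)
    return acc / n_permutations


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_asv_table(path) -> ASVTable:
    """Read the TSV dialect: asv_id, taxonomy columns, then sample columns."""
    df = pd.read_csv(path, sep="\t", dtype={"asv_id": str})
    if "asv_id" not in df.columns:
        raise DetectError("ASV table missing column 'asv_id'")
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise DetectError(f"ASV table missing taxonomy column(s): {', '.join(missing)}")
    df = df.set_index("asv_id")
    tax = df[TAXONOMY_COLUMNS].copy()
    for col in TAXONOMY_COLUMNS[:-1]:
        tax[col] = tax[col].fillna("").astype(str)
    sample_cols = [c for c in df.columns if c not in TAXONOMY_COLUMNS]
    reads = df[sample_cols].astype(np.int64)
    return ASVTable(reads=reads, taxonomy=tax)


def write_asv_table(table: ASVTable, path) -> None:
    tax = table.taxonomy[TAXONOMY_COLUMNS]
    out = pd.concat([tax, table.reads], axis=1)
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t")


def read_sample_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, dtype=str)
    return SampleMetadata(table=df)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, index=False)
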