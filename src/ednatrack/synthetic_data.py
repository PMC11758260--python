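"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: analytic flow
fields with the oscillatory-plus-residual structure of tidal coastal
currents (uniform, single-constituent tidal, and a masked bay with a
divergence-free gyre), station layouts, and metabarcoding survey tables
with planted species detections, control leakage, singleton noise,
contaminant taxa and shallow taxonomic assignments.  Each generator is
deterministic under its seed, and :class:`SurveyTruth` carries exact
bookkeeping of every injected artefact so filter attrition can be checked
against it.

The default tidal constituent is M2-like (period 44 712 s); survey
defaults mirror a year-long, ten-station monthly campaign with an
eleven-species target pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .edna_detect import ASVTable, SampleMetadata, TAXONOMY_COLUMNS
from .flowfields import FlowField

__all__ = [
    "M2_PERIOD_S",
    "SurveyTruth",
    "make_uniform_field",
    "make_tidal_field",
    "make_bay_field",
    "make_survey",
    "DEFAULT_SPECIES",
    "DEFAULT_CONTAMINANTS",
]

M2_PERIOD_S = 44_712.0

# Elasmobranch target pool: genus/species pairs typical of Welsh SAC surveys.
DEFAULT_SPECIES = [
    ("Scyliorhinus", "Scyliorhinus canicula"),
    ("Scyliorhinus", "Scyliorhinus stellaris"),
    ("Galeorhinus", "Galeorhinus galeus"),
    ("Mustelus", "Mustelus asterias"),
    ("Squatina", "Squatina squatina"),
    ("Raja", "Raja clavata"),
    ("Raja", "Raja microocellata"),
    ("Raja", "Raja undulata"),
    ("Raja", "Raja montagui"),
    ("Raja", "Raja brachyura"),
    ("Dasyatis", "Dasyatis pastinaca"),
]

# Indian Ocean elasmobranchs: plausible cross-project lab contaminants.
DEFAULT_CONTAMINANTS = [
    ("Carcharhinus", "Carcharhinus melanopterus"),
    ("Taeniura", "Taeniura lymma"),
]

_MONTHS = ["Sep", "Oct", "Nov", "Dec", "Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug"]


# ---------------------------------------------------------------------------
# flow fields
# ---------------------------------------------------------------------------

def _grid(extent: float, resolution: float) -> np.ndarray:
    n = int(round(extent / resolution)) + 1
    return np.arange(n) * resolution


def make_uniform_field(
    u0: float,
    v0: float,
    extent: float = 60_000.0,
    duration: float = 345_600.0,
    resolution: float = 5_000.0,
    time_step: float = 3_600.0,
) -> FlowField:
    """Constant (u0, v0) everywhere, all wet: the closed-form test bed."""
    x = _grid(extent, resolution)
    times = np.arange(0.0, duration + time_step / 2, time_step)
    shape = (times.size, x.size, x.size)
    return FlowField(
        x_coords=x,
        y_coords=x.copy(),
        times=times,
        u=np.full(shape, float(u0)),
        v=np.full(shape, float(v0)),
    )


def make_tidal_field(
    U: float,
    V: float,
    period: float = M2_PERIOD_S,
    phase: float = 0.0,
    residual: tuple[float, float] = (0.0, 0.0),
    extent: float = 60_000.0,
    duration: float = 345_600.0,
    resolution: float = 5_000.0,
    time_step: float = 600.0,
) -> FlowField:
    """Spatially uniform single-constituent tide plus a steady residual.

    u(t) = ur + U sin(2 pi t / period + phase)
    v(t) = vr + V cos(2 pi t / period + phase)

    With U = V and zero phase the hodograph is rotary (constant speed);
    over an integer number of periods the oscillatory part integrates to
    zero, leaving only the residual drift.
    """
    if U < 0 or V < 0:
        raise ValueError("tidal amplitudes U, V must be >= 0")
    if period <= 0:
        raise ValueError("period must be positive")
    x = _grid(extent, resolution)
    times = np.arange(0.0, duration + time_step / 2, time_step)
    omega = 2.0 * np.pi / period
    ut = residual[0] + U * np.sin(omega * times + phase)
    vt = residual[1] + V * np.cos(omega * times + phase)
    ny = nx = x.size
    u = np.broadcast_to(ut[:, None, None], (times.size, ny, nx)).copy()
    v = np.broadcast_to(vt[:, None, None], (times.size, ny, nx)).copy()
    return FlowField(x_coords=x, y_coords=x.copy(), times=times, u=u, v=v)


def make_bay_field(
    extent: float = 20_000.0,
    resolution: float = 500.0,
    duration: float = 345_600.0,
    time_step: float = 1_800.0,
    peak_speed: float = 0.4,
    period: float = M2_PERIOD_S,
    residual_fraction: float = 0.05,
    phase: float = 0.0,
) -> FlowField:
    """A masked square bay with a tidally modulated, divergence-free gyre.

    The interior flow derives from the streamfunction
    ``psi = Psi sin(pi x / L) sin(pi y / L)`` (u = dpsi/dy, v = -dpsi/dx),
    so it is divergence-free by construction and has no flow normal to the
    domain edge; the outermost ring of nodes is land (wet_mask false,
    velocities zero).  The whole pattern is modulated in time by
    ``residual_fraction + sin(2 pi t / period + phase)``: an oscillatory
    tide plus a weak residual circulation.  Because the modulation only
    rescales speed along fixed streamlines, particles circulate on closed
    loops and stay inside the bay indefinitely — a well-behaved stand-in
    for a semi-enclosed coastal embayment.
    """
    x = _grid(extent, resolution)
    L = float(x[-1])
    times = np.arange(0.0, duration + time_step / 2, time_step)
    X, Y = np.meshgrid(x, x, indexing="xy")
    # scale Psi so the peak spatial speed is peak_speed at unit modulation
    psi_amp = peak_speed * L / np.pi
    k = np.pi / L
    u_s = psi_amp * k * np.sin(k * X) * np.cos(k * Y)  # dpsi/dy
    v_s = -psi_amp * k * np.cos(k * X) * np.sin(k * Y)  # -dpsi/dx

    wet = np.ones((x.size, x.size), dtype=bool)
    wet[0, :] = wet[-1, :] = False
    wet[:, 0] = wet[:, -1] = False
    u_s = np.where(wet, u_s, 0.0)
    v_s = np.where(wet, v_s, 0.0)

    mod = residual_fraction + np.sin(2.0 * np.pi * times / period + phase)
    u = mod[:, None, None] * u_s[None, :, :]
    v = mod[:, None, None] * v_s[None, :, :]
    return FlowField(x_coords=x, y_coords=x.copy(), times=times, u=u, v=v, wet_mask=wet)


def bay_stations(n_stations: int, extent: float = 20_000.0, ring_fraction: float = 0.25) -> pd.DataFrame:
    """Station layout on a ring around the bay centre (mid-gyre, away from land)."""
    centre = extent / 2.0
    r = ring_fraction * extent
    theta = 2.0 * np.pi * np.arange(n_stations) / n_stations
    return pd.DataFrame(
        {
            "station_id": [f"S{i + 1:02d}" for i in range(n_stations)],
            "name": [f"station {i + 1}" for i in range(n_stations)],
            "x_m": centre + r * np.cos(theta),
            "y_m": centre + r * np.sin(theta),
        }
    )


# ---------------------------------------------------------------------------
# surveys
# ---------------------------------------------------------------------------

@dataclass
class SurveyTruth:
    """Exact bookkeeping of everything planted into a synthetic survey."""

    planted: pd.DataFrame  # columns: species, station_id, month
    leakage_events: list = dc_field(default_factory=list)  # (asv_id, sample_id)
    singleton_events: list = dc_field(default_factory=list)  # (asv_id, sample_id)
    contaminant_rows: list = dc_field(default_factory=list)  # asv_ids
    subgenus_rows: list = dc_field(default_factory=list)  # asv_ids dropped by the genus rule
    genus_only_rows: list = dc_field(default_factory=list)  # asv_ids retained but non-species
    contaminant_list: set = dc_field(default_factory=set)  # species names to pass to the filter

    def detection_matrix(self) -> pd.DataFrame:
        """Planted species x station x month detections, sorted for comparison."""
        return (
            self.planted[["species", "station_id", "month"]]
            .drop_duplicates()
            .sort_values(["species", "station_id", "month"])
            .reset_index(drop=True)
        )


def _lognormal_reads(rng: np.random.Generator, n: int) -> np.ndarray:
    """Log-normal read counts floored at 2 (a planted detection is never a singleton)."""
    return np.maximum(2, np.round(rng.lognormal(mean=5.0, sigma=1.2, size=n))).astype(np.int64)


def make_survey(
    n_stations: int = 10,
    n_months: int = 12,
    species_pool: int = 11,
    detection_prob: float = 0.05,
    leakage_rate: float = 0.0,
    singleton_rate: float = 0.0,
    contaminant_rate: float = 0.1,
    seed: int = 0,
    sac_label: str = "SAC",
) -> tuple[ASVTable, SampleMetadata, SurveyTruth]:
    """Generate an ASV table + metadata + ground truth for one survey.

    One water sample and one paired field control per station-month (240
    columns at the 10 x 12 defaults).  Planted detections draw
    log-normal read counts floored at 2; ``leakage_rate`` copies a planted
    cell's ASV into its paired control (so control subtraction removes it);
    ``singleton_rate`` injects 1-read cells into otherwise-empty target
    cells (so singleton removal zeroes exactly those); contaminant,
    family-level and genus-only rows exercise the taxonomy rules; abundant
    human and teleost rows exercise the target-class filter.  Field
    controls carry no reads other than leakage, keeping the attrition
    bookkeeping exact.
    """
    for name, rate in (
        ("detection_prob", detection_prob),
        ("leakage_rate", leakage_rate),
        ("singleton_rate", singleton_rate),
        ("contaminant_rate", contaminant_rate),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if n_stations < 1 or n_months < 1 or species_pool < 1:
        raise ValueError("n_stations, n_months and species_pool must be >= 1")
    if species_pool > len(DEFAULT_SPECIES):
        raise ValueError(f"species_pool limited to {len(DEFAULT_SPECIES)} named species")

    rng = np.random.default_rng(seed)
    stations = [f"S{i + 1:02d}" for i in range(n_stations)]
    months = [_MONTHS[m % 12] for m in range(n_months)]
    species = DEFAULT_SPECIES[:species_pool]

    # --- metadata: one sample + one paired field control per station-month
    rows = []
    for st in stations:
        for mo in months:
            sid = f"{sac_label}-{st}-{mo}-S"
            cid = f"{sac_label}-{st}-{mo}-C"
            rows.append({"sample_id": sid, "station_id": st, "month": mo,
                         "type": "sample", "paired_control_id": cid})
            rows.append({"sample_id": cid, "station_id": st, "month": mo,
                         "type": "field_control", "paired_control_id": ""})
    meta_df = pd.DataFrame(rows)
    sample_ids = meta_df.loc[meta_df["type"] == "sample", "sample_id"].tolist()
    columns = meta_df["sample_id"].tolist()

    # --- taxonomy rows
    tax_rows: list[dict] = []

    def add_row(asv_id, cls, order, family, genus, sp, conf):
        tax_rows.append({"asv_id": asv_id, "class": cls, "order": order, "family": family,
                         "genus": genus, "species": sp, "confidence": conf})

    species_asvs = []
    for i, (genus, sp) in enumerate(species):
        asv = f"ASV{i + 1:03d}"
        species_asvs.append(asv)
        add_row(asv, "Elasmobranchii", "", "", genus, sp, round(float(rng.uniform(60, 100)), 1))

    genus_only_asv = "ASV_GEN1"
    add_row(genus_only_asv, "Elasmobranchii", "Rajiformes", "Rajidae", "Raja", "", 45.0)
    family_only_asv = "ASV_FAM1"
    add_row(family_only_asv, "Elasmobranchii", "Rajiformes", "Rajidae", "", "", 55.0)

    contaminant_asvs = []
    for i, (genus, sp) in enumerate(DEFAULT_CONTAMINANTS):
        asv = f"ASV_CON{i + 1}"
        contaminant_asvs.append(asv)
        add_row(asv, "Elasmobranchii", "", "", genus, sp, round(float(rng.uniform(60, 100)), 1))

    bycatch = [
        ("ASV_HUM1", "Mammalia", "Primates", "Hominidae", "Homo", "Homo sapiens"),
        ("ASV_TEL1", "Actinopteri", "Clupeiformes", "Clupeidae", "Clupea", "Clupea harengus"),
        ("ASV_TEL2", "Actinopteri", "Pleuronectiformes", "Pleuronectidae", "Pleuronectes",
         "Pleuronectes platessa"),
    ]
    for asv, cls, order, family, genus, sp in bycatch:
        add_row(asv, cls, order, family, genus, sp, round(float(rng.uniform(60, 100)), 1))

    tax = pd.DataFrame(tax_rows).set_index("asv_id")[TAXONOMY_COLUMNS]
    reads = pd.DataFrame(
        np.zeros((len(tax), len(columns)), dtype=np.int64), index=tax.index, columns=columns
    )

    truth = SurveyTruth(
        planted=pd.DataFrame(columns=["species", "station_id", "month"]),
        contaminant_rows=list(contaminant_asvs),
        subgenus_rows=[family_only_asv],
        genus_only_rows=[genus_only_asv],
        contaminant_list={sp for _, sp in DEFAULT_CONTAMINANTS},
    )

    # --- planted species detections
    planted_records = []
    for asv, (genus, sp) in zip(species_asvs, species):
        hit = rng.random((n_stations, n_months)) < detection_prob
        for si, st in enumerate(stations):
            for mi, mo in enumerate(months):
                if hit[si, mi]:
                    sid = f"{sac_label}-{st}-{mo}-S"
                    reads.loc[asv, sid] = _lognormal_reads(rng, 1)[0]
                    planted_records.append({"species": sp, "station_id": st, "month": mo})
    truth.planted = pd.DataFrame(planted_records, columns=["species", "station_id", "month"])

    # --- leakage: planted cells whose ASV also shows up in the paired control
    pairing = dict(zip(meta_df.loc[meta_df["type"] == "sample", "sample_id"],
                       meta_df.loc[meta_df["type"] == "sample", "paired_control_id"]))
    for asv in species_asvs:
        for sid in sample_ids:
            if reads.loc[asv, sid] > 0 and rng.random() < leakage_rate:
                cid = pairing[sid]
                reads.loc[asv, cid] = max(1, int(reads.loc[asv, sid] // 10))
                truth.leakage_events.append((asv, sid))

    # --- singleton noise: 1-read cells in otherwise-empty target cells
    for asv in species_asvs:
        for sid in sample_ids:
            if reads.loc[asv, sid] == 0 and rng.random() < singleton_rate:
                reads.loc[asv, sid] = 1
                truth.singleton_events.append((asv, sid))

    # --- contaminant and shallow-assignment rows (reads >= 2, never singletons)
    for asv in contaminant_asvs:
        for sid in sample_ids:
            if rng.random() < contaminant_rate:
                reads.loc[asv, sid] = _lognormal_reads(rng, 1)[0]
    for asv in (genus_only_asv, family_only_asv):
        for sid in sample_ids:
            if rng.random() < detection_prob:
                reads.loc[asv, sid] = _lognormal_reads(rng, 1)[0]

    # --- non-target by-catch: abundant in samples only (controls stay clean)
    for asv, *_ in bycatch:
        dens = 0.9 if asv == "ASV_HUM1" else 0.4
        for sid in sample_ids:
            if rng.random() < dens:
                reads.loc[asv, sid] = _lognormal_reads(rng, 1)[0] * (10 if asv == "ASV_HUM1" else 1)

    return ASVTable(reads=reads, taxonomy=tax), SampleMetadata(table=meta_df), truth
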