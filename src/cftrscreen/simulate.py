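"""Synthetic inputs for every pipeline stage.

The generators emulate the data the pipeline would see from a real
pooled interaction screen and its follow-up assays:

* post-sort prey read counts in which a bait's true interactors are
  enriched, promiscuous "frequent flier" preys are enriched in every
  screen, and background preys sit at a low negative-binomial baseline
  over two technical replicates;
* 384-well plate image summaries with a smooth spatial intensity
  gradient, well-level siRNA effects and injected QC failures;
* membrane-potential dye traces with baseline, agonist-response and
  inhibitor-decay segments;
* organoid area-versus-time swelling curves.

Every generator is deterministic given its config seed, and each returns
a truth table recording the role of every ORF / well so downstream
calling can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .quant import CountTable, ORFReference

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# pooled-screen sequencing
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimConfig:
    """Conditions for a simulated pooled interaction screen.

    Counts are negative-binomial: background preys have mean
    ``base_mean``, a bait's true interactors ``base_mean * enrichment_fold``
    (the post-sort enrichment), and frequent fliers
    ``base_mean * flier_fold`` in *every* screen regardless of bait.
    ``dispersion`` is the NB size parameter (variance = m + m^2/size).
    """

    n_orfs: int = 1000
    n_true_interactors: int = 20
    n_fliers: int = 5
    enrichment_fold: float = 50.0
    flier_fold: float = 100.0
    base_mean: float = 2.0
    dispersion: float = 2.0
    n_replicates: int = 2
    n_control_screens: int = 9
    orf_length: int = 300
    read_length: int = 75
    reads_per_orf_unit: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_interactors + self.n_fliers > self.n_orfs:
            raise ValueError("role counts exceed n_orfs")
        if self.enrichment_fold < 1 or self.flier_fold < 1:
            raise ValueError("fold parameters must be >= 1")
        if self.dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("base_mean and dispersion must be positive")
        if self.n_control_screens < 2:
            raise ValueError(
                "at least 2 control screens are required: the rank product "
                "is a multi-screen consensus"
            )
        if self.read_length > self.orf_length:
            raise ValueError("read_length exceeds orf_length")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial with given mean vector and size (dispersion)."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def make_reference(
    n_orfs: int, orf_length: int, rng: np.random.Generator, k: int = 31
) -> ORFReference:
    """Random A/C/G/T ORF reference with ids ORF0000, ORF0001, ..."""
    entries = tuple(
        (f"ORF{i:04d}", "".join(rng.choice(_BASES, size=orf_length)))
        for i in range(n_orfs)
    )
    return ORFReference(entries=entries, k=k)


def _role_table(config: ScreenSimConfig, orf_ids: Sequence[str]) -> pd.DataFrame:
    roles = np.array(["background"] * config.n_orfs, dtype=object)
    roles[: config.n_true_interactors] = "true_interactor"
    roles[
        config.n_true_interactors : config.n_true_interactors + config.n_fliers
    ] = "flier"
    return pd.DataFrame({"orf_id": list(orf_ids), "role": roles})


def _expected_means(config: ScreenSimConfig, roles: np.ndarray) -> np.ndarray:
    means = np.full(config.n_orfs, config.base_mean)
    means[roles == "true_interactor"] = config.base_mean * config.enrichment_fold
    means[roles == "flier"] = config.base_mean * config.flier_fold
    return means * config.reads_per_orf_unit


@dataclass
class SimulatedScreen:
    """One bait screen: reference, per-replicate reads, counts and truth."""

    bait: str
    reference: ORFReference
    reads: list[list[str]]
    counts: CountTable
    truth: pd.DataFrame


def simulate_screen_counts(
    config: ScreenSimConfig, rng: np.random.Generator | None = None
) -> tuple[CountTable, pd.DataFrame]:
    """Draw the per-ORF, per-replicate count matrix only (no reads)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    orf_ids = [f"ORF{i:04d}" for i in range(config.n_orfs)]
    truth = _role_table(config, orf_ids)
    means = _expected_means(config, truth["role"].to_numpy())
    counts = np.column_stack(
        [_nb_draw(rng, means, config.dispersion) for _ in range(config.n_replicates)]
    )
    table = CountTable(
        orf_ids=orf_ids,
        counts=counts.astype(np.int64),
        replicates=[f"rep{j + 1}" for j in range(config.n_replicates)],
    )
    return table, truth


def simulate_screen(config: ScreenSimConfig, bait: str = "bait") -> SimulatedScreen:
    """Simulate one bait screen down to the reads.

    Per-ORF counts follow the negative-binomial role model; each count
    becomes that many error-free forward-strand substrings of the ORF
    sequence, of length ``read_length``, at uniform random offsets.
    """
    rng = np.random.default_rng(config.seed)
    reference = make_reference(config.n_orfs, config.orf_length, rng)
    table, truth = simulate_screen_counts(config, rng)
    reads: list[list[str]] = []
    max_off = config.orf_length - config.read_length
    seqs = [seq for _, seq in reference.entries]
    for j in range(config.n_replicates):
        rep_reads: list[str] = []
        for i, n in enumerate(table.counts[:, j]):
            if n == 0:
                continue
            offsets = rng.integers(0, max_off + 1, size=n)
            rep_reads.extend(
                seqs[i][off : off + config.read_length] for off in offsets
            )
        # shuffle so read order carries no information about the ORF
        order = rng.permutation(len(rep_reads))
        reads.append([rep_reads[t] for t in order])
    return SimulatedScreen(
        bait=bait, reference=reference, reads=reads, counts=table, truth=truth
    )


def simulate_control_screens(
    config: ScreenSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CPM matrix over ``n_control_screens`` unrelated-bait screens.

    Fliers are enriched in every screen; each screen also gets its own
    independent set of screen-specific interactors (drawn among the
    background preys) so control screens look like real screens, plus an
    independently resampled background.  Returns (cpm wide frame indexed
    by orf_id with one column per screen, truth table).
    """
    rng = np.random.default_rng(config.seed)
    orf_ids = [f"ORF{i:04d}" for i in range(config.n_orfs)]
    truth = _role_table(config, orf_ids)
    roles = truth["role"].to_numpy()
    background_idx = np.flatnonzero(roles == "background")
    cpm_cols = {}
    for s in range(config.n_control_screens):
        means = np.full(config.n_orfs, config.base_mean)
        means[roles == "flier"] = config.base_mean * config.flier_fold
        # screen-specific true interactors of the control bait
        if config.n_true_interactors > 0 and len(background_idx) > 0:
            k = min(config.n_true_interactors, len(background_idx))
            own = rng.choice(background_idx, size=k, replace=False)
            means[own] = config.base_mean * config.enrichment_fold
        counts = _nb_draw(rng, means * config.reads_per_orf_unit, config.dispersion)
        total = counts.sum()
        cpm_cols[f"screen{s + 1}"] = (
            counts * 1e6 / total if total > 0 else np.zeros(config.n_orfs)
        )
    cpm = pd.DataFrame(cpm_cols, index=pd.Index(orf_ids, name="orf_id"))
    return cpm, truth


# ---------------------------------------------------------------------------
# high-content traffic-screen plates
# ---------------------------------------------------------------------------


@dataclass
class PlateSimConfig:
    """Conditions for simulated traffic-screen plates.

    Per-image well medians are ``base_intensity * gradient(r, c) *
    (1 + effect * noise_cv) + noise`` with Gaussian noise of SD
    ``base_intensity * noise_cv``, so ``effect_wells`` values are in
    units of the per-image noise SD.  A fraction ``qc_fail_rate`` of
    images is injected with a QC failure (low cell count, out of focus,
    or negligible reporter expression).  Column 1 wells carry the
    non-targeting control siRNA (siNeg1).
    """

    n_rows: int = 16
    n_cols: int = 24
    base_intensity: float = 1000.0
    gradient_amplitude: float = 0.2
    gradient_shape: str = "linear"  # or "sine"
    noise_cv: float = 0.05
    effect_wells: dict[tuple[int, int], float] = field(default_factory=dict)
    n_cells_mean: float = 400.0
    images_per_well: int = 4
    n_replicates: int = 4
    qc_fail_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.qc_fail_rate <= 1:
            raise ValueError("qc_fail_rate must be in [0, 1]")
        for (r, c) in self.effect_wells:
            if not (1 <= r <= self.n_rows and 1 <= c <= self.n_cols):
                raise ValueError(f"effect well ({r}, {c}) off the plate")
        if self.gradient_shape not in ("linear", "sine"):
            raise ValueError("gradient_shape must be 'linear' or 'sine'")


def _gradient(config: PlateSimConfig) -> np.ndarray:
    """Smooth multiplicative spatial gradient, mean approximately 1."""
    r = np.arange(config.n_rows, dtype=float)
    c = np.arange(config.n_cols, dtype=float)
    rn = (r - r.mean()) / max(r.max(), 1.0)
    cn = (c - c.mean()) / max(c.max(), 1.0)
    if config.gradient_shape == "linear":
        surface = rn[:, None] + cn[None, :]
    else:
        surface = np.sin(np.pi * rn)[:, None] + np.cos(np.pi * cn)[None, :]
    return 1.0 + config.gradient_amplitude * surface


def default_layout(config: PlateSimConfig) -> pd.DataFrame:
    """One siRNA per well; column 1 is the non-targeting control siNeg1.

    Test wells are named ``si_<gene>_1`` / ``si_<gene>_2``: consecutive
    well pairs share a gene, mirroring two siRNAs per gene target.
    """
    rows = []
    gene_counter = 0
    pair = 0
    for r in range(1, config.n_rows + 1):
        for c in range(1, config.n_cols + 1):
            if c == 1:
                rows.append((r, c, "siNeg1", "NEG", True))
                continue
            gene = f"GENE{gene_counter:04d}"
            rows.append((r, c, f"si_{gene}_{pair + 1}", gene, False))
            pair += 1
            if pair == 2:
                pair = 0
                gene_counter += 1
    return pd.DataFrame(
        rows, columns=["row", "col", "sirna_id", "gene", "is_negative_control"]
    )


def simulate_plate(
    config: PlateSimConfig, layout: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate image-level well summaries for all replicate plates.

    Returns ``(measures, layout, truth)``.  ``measures`` has one row per
    image with the PlateMeasure columns consumed by the traffic module;
    ``truth`` records each well's injected effect and each image's
    injected QC failure mode (or "ok").
    """
    rng = np.random.default_rng(config.seed)
    if layout is None:
        layout = default_layout(config)
    grad = _gradient(config)
    sigma = config.base_intensity * config.noise_cv

    records = []
    truth_records = []
    fail_modes = np.array(["low_cells", "out_of_focus", "low_expression"])
    for rep in range(1, config.n_replicates + 1):
        plate_id = f"plate1_rep{rep}"
        for _, wrow in layout.iterrows():
            r, c = int(wrow["row"]), int(wrow["col"])
            effect = config.effect_wells.get((r, c), 0.0)
            mean = (
                config.base_intensity
                * grad[r - 1, c - 1]
                * (1.0 + effect * config.noise_cv)
            )
            for img in range(1, config.images_per_well + 1):
                traffic = mean + rng.normal(0.0, sigma)
                expression = config.base_intensity * (
                    1.0 + rng.normal(0.0, config.noise_cv)
                )
                n_cells = int(rng.poisson(config.n_cells_mean))
                focus = float(np.clip(rng.normal(0.9, 0.05), 0.0, 1.0))
                fail = "ok"
                if rng.random() < config.qc_fail_rate:
                    fail = str(rng.choice(fail_modes))
                    if fail == "low_cells":
                        n_cells = int(rng.integers(0, 100))
                    elif fail == "out_of_focus":
                        focus = float(rng.uniform(0.0, 0.3))
                    else:
                        expression = float(rng.uniform(0.0, 0.05 * config.base_intensity))
                records.append(
                    (
                        plate_id,
                        r,
                        c,
                        f"rep{rep}",
                        img,
                        n_cells,
                        traffic,
                        expression,
                        focus,
                        wrow["sirna_id"],
                        wrow["gene"],
                        bool(wrow["is_negative_control"]),
                    )
                )
                truth_records.append((plate_id, r, c, img, effect, fail))
    measures = pd.DataFrame(
        records,
        columns=[
            "plate_id",
            "row",
            "col",
            "replicate",
            "image_index",
            "n_cells",
            "median_traffic",
            "median_expression",
            "focus_metric",
            "sirna_id",
            "gene",
            "is_negative_control",
        ],
    )
    truth = pd.DataFrame(
        truth_records,
        columns=["plate_id", "row", "col", "image_index", "effect", "qc_fail"],
    )
    return measures, layout, truth


# ---------------------------------------------------------------------------
# fluorescence traces and swelling curves
# ---------------------------------------------------------------------------


@dataclass
class TraceSimConfig:
    """Membrane-potential dye trace: baseline, agonist rise, inhibitor decay.

    The trace starts with ``n_baseline_scans`` reads at ``baseline_rfu``,
    rises after the agonist (forskolin) event to ``baseline * (1 +
    response_amplitude)``, and after the inhibitor event decays to
    ``peak * (1 - inhibitor_drop)``.  Event times are explicit columns in
    the output, not inferred from the signal.
    """

    n_baseline_scans: int = 5
    n_response_scans: int = 5
    n_inhibitor_scans: int = 5
    baseline_rfu: float = 100.0
    response_amplitude: float = 0.5
    inhibitor_drop: float = 0.3
    noise_sd: float = 0.0
    scan_interval: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_baseline_scans < 4:
            raise ValueError("at least 4 baseline scans are required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_trace(config: TraceSimConfig, responsive: bool = True):
    """Simulate one trace; returns an :class:`~cftrscreen.assays.AssayTrace`.

    ``responsive=False`` yields a flat trace (up to noise) with the same
    event markers, emulating a cell line without functional channel.
    """
    from .assays import AssayTrace  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed)
    n_total = (
        config.n_baseline_scans + config.n_response_scans + config.n_inhibitor_scans
    )
    times = np.arange(n_total) * config.scan_interval
    base = config.baseline_rfu
    values = np.full(n_total, base, dtype=float)
    i_fsk = config.n_baseline_scans
    i_inh = config.n_baseline_scans + config.n_response_scans
    if responsive:
        peak = base * (1.0 + config.response_amplitude)
        # ramp to peak over the response segment, holding the peak at the
        # last pre-inhibitor scan
        ramp = np.linspace(base, peak, config.n_response_scans + 1)[1:]
        values[i_fsk:i_inh] = ramp
        floor = peak * (1.0 - config.inhibitor_drop)
        decay = np.linspace(peak, floor, config.n_inhibitor_scans + 1)[1:]
        values[i_inh:] = decay
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=n_total)
    events = [
        ("fsk", float(times[i_fsk] - config.scan_interval / 2)),
        ("inhibitor", float(times[i_inh] - config.scan_interval / 2)),
    ]
    return AssayTrace(times=times, values=values, events=events)


def simulate_swelling(
    t_end: float = 60.0,
    n_points: int = 13,
    final_area: float = 160.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Organoid swelling curve: % of initial area, linear rise from 100.

    Returns an :class:`~cftrscreen.assays.AssayTrace` in minutes with a
    ``fsk`` event at t = 0 (stimulation starts the recording).
    """
    from .assays import AssayTrace

    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_end, n_points)
    values = 100.0 + (final_area - 100.0) * times / t_end
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_points)
        values[0] = 100.0
    return AssayTrace(times=times, values=values, events=[("fsk", 0.0)])
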