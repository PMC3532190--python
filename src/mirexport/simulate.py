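"""Synthetic small-RNA study generator with full ground truth.

Emulates a paired cell/EV deep-sequencing experiment — optionally with a
second, transfected condition in which one miRNA is overexpressed to a
large fraction of the read pool — so that every downstream module can be
exercised against known truth:

* a hairpin reference with one mature arm per hairpin and well-separated
  mature sequences (pairwise Hamming distance >= 5) for unambiguous
  mapping;
* cellular miRNA proportions drawn from a log-normal (heavy-tailed, as in
  real libraries where a handful of miRNAs dominate);
* per-miRNA export propensities e_i on the log2 scale drawn from a
  three-component mixture: a baseline centred at zero, a strongly
  exported minority (miR-451-like) and a retained minority. EV
  proportions are the cellular proportions tilted by 2^e_i and
  renormalized — because proportions are compositional, realized
  log2(EV/cell) ratios equal e_i minus a common constant, so recovery is
  assessed after median-centering;
* reads sampled multinomially with isomiR end offsets, per-base
  substitution errors and an appended 3' adapter, written as FASTQ-ready
  read sets;
* derived Ct tables (qPCR) and multi-platform dataset panels for the
  rank-concordance module.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .refio import (
    DEFAULT_ADAPTER,
    Hairpin,
    HairpinReference,
    MatureArm,
    Read,
    ReadSet,
)
from .quantify import CountTable
from .cross_dataset import DatasetMeasure, Platform
from .qpcr import CtTable

__all__ = [
    "SpikeConfig",
    "SimulationConfig",
    "GroundTruth",
    "simulate_reference",
    "simulate_libraries",
    "simulate_count_tables",
    "simulate_ct_table",
    "simulate_dataset_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# default isomiR end-offset spectrum: canonical form carries half the
# reads, the remainder spread over small 5'/3' shifts
DEFAULT_ISOMIR_OFFSETS: dict[tuple[int, int], float] = {
    (0, 0): 0.50,
    (0, -1): 0.15,
    (0, 1): 0.10,
    (-1, 0): 0.10,
    (1, 0): 0.05,
    (0, -2): 0.05,
    (1, -1): 0.05,
}


@dataclass(frozen=True)
class SpikeConfig:
    """Overexpression spike: the transfected miRNA's share of each pool.

    Defaults echo an overexpressed miRNA reaching 32% of cellular and 44%
    of EV reads.
    """

    mirna_id: str | None = None  # None -> first mature in the reference
    cell_fraction: float = 0.32
    ev_fraction: float = 0.44

    def __post_init__(self) -> None:
        for f in (self.cell_fraction, self.ev_fraction):
            if not (0.0 < f < 1.0):
                raise ValueError(f"spike fraction {f} must be in (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic experiment.

    The defaults describe a four-library design (cells/EVs x
    non-transfected/transfected) with 10^6 reads per library, ~150
    expressed miRNAs with log-normal abundances spanning several orders of
    magnitude, a ~12% strongly exported and ~5% retained minority, an
    overexpression spike, a canonical-isomiR mass of 0.5 and a 0.1%
    per-base substitution error rate on 36 nt reads.
    """

    n_mirnas: int = 150
    hairpin_length: int = 80
    mature_length_range: tuple[int, int] = (20, 23)
    # log-normal over cellular proportions (natural-log parameters)
    abundance_log_mean: float = 0.0
    abundance_log_sd: float = 2.0
    # export-propensity mixture (log2 units)
    baseline_sd: float = 1.5
    p_exported: float = 0.12
    exported_shift: float = 5.0
    exported_sd: float = 2.0
    p_retained: float = 0.05
    retained_shift: float = 2.0
    retained_sd: float = 0.7
    spike: SpikeConfig | None = SpikeConfig()
    reads_per_library: int = 1_000_000
    isomir_offsets: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_ISOMIR_OFFSETS)
    )
    error_rate: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        if self.reads_per_library < 1:
            raise ValueError("reads_per_library must be > 0")
        total = sum(self.isomir_offsets.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"isomiR offset probabilities sum to {total}, not 1")
        if not (0.0 <= self.p_exported + self.p_retained <= 1.0):
            raise ValueError("mixture probabilities must sum to <= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    cell_props: pd.Series  # per condition-free (non-transfected) pool
    ev_props: pd.Series
    e: pd.Series  # per-miRNA log2 export propensity
    spike: SpikeConfig | None = None
    cell_props_spiked: pd.Series | None = None
    ev_props_spiked: pd.Series | None = None
    read_records: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def mature_ids(self) -> list[str]:
        return list(self.cell_props.index)

    def true_log2_ratio(self, condition: str = "nt") -> pd.Series:
        """Realized log2(EV/cell) of the proportion vectors (NaN at zeros)."""
        if condition == "tf" and self.cell_props_spiked is not None:
            cell, ev = self.cell_props_spiked, self.ev_props_spiked
        else:
            cell, ev = self.cell_props, self.ev_props
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.log2(ev / cell)
        return pd.Series(np.where((cell > 0) & (ev > 0), r, np.nan), index=cell.index)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(rng.choice(_BASES, size=length)).decode()


def _hamming_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    return sum(x != y for x, y in zip(a[:n], b[:n]))


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> HairpinReference:
    """Random hairpins, one 20–23 nt mature arm each, unambiguous by design.

    Mature sequences are rejection-sampled to keep every pair at Hamming
    distance >= 5 (over the shared prefix), so no read within the 2-mismatch
    alignment cap can be placed on the wrong arm. The arm is embedded with
    at least 3 nt of flank on both sides so small isomiR end shifts stay on
    the hairpin.
    """
    rng = rng if rng is not None else config.rng()
    lo, hi = config.mature_length_range
    if config.hairpin_length < hi + 6:
        raise ValueError("hairpin_length too small for mature arm plus flanks")
    matures: list[str] = []
    max_attempts = 200 * config.n_mirnas + 1000
    attempts = 0
    while len(matures) < config.n_mirnas:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "rejection sampling failed to place well-separated mature "
                "sequences; use longer matures or fewer miRNAs"
            )
        cand = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        if all(_hamming_prefix(cand, m) >= 5 for m in matures):
            matures.append(cand)
    entries = []
    width = max(4, len(str(config.n_mirnas)))
    for i, mat in enumerate(matures):
        flank_total = config.hairpin_length - len(mat)
        start0 = int(rng.integers(3, flank_total - 3 + 1))  # 0-based, >=3 nt flanks
        left = _random_seq(rng, start0)
        right = _random_seq(rng, flank_total - start0)
        seq = left + mat + right
        hp_id = f"hp-{i:0{width}d}"
        mid = f"mir-{i:0{width}d}"
        entries.append(
            Hairpin(hp_id, seq, (MatureArm(mid, start0 + 1, start0 + len(mat)),))
        )
    return HairpinReference(tuple(entries))


def _export_propensities(
    config: SimulationConfig, rng: np.random.Generator, mature_ids: Sequence[str]
) -> pd.Series:
    n = len(mature_ids)
    u = rng.random(n)
    e = rng.normal(0.0, config.baseline_sd, size=n)
    exported = u < config.p_exported
    retained = (u >= config.p_exported) & (u < config.p_exported + config.p_retained)
    e[exported] = rng.normal(config.exported_shift, config.exported_sd, size=int(exported.sum()))
    e[retained] = rng.normal(-config.retained_shift, config.retained_sd, size=int(retained.sum()))
    return pd.Series(e, index=list(mature_ids))


def _spiked_props(props: pd.Series, mirna: str, fraction: float) -> pd.Series:
    if fraction >= 1.0:
        raise ValueError("spike fraction must be < 1")
    out = props.copy()
    others = out.index != mirna
    rest = out[others].sum()
    out.loc[others] = out[others] * (1.0 - fraction) / rest
    out.loc[mirna] = fraction
    return out


def _truth(
    config: SimulationConfig, ref: HairpinReference, rng: np.random.Generator
) -> GroundTruth:
    mature_ids = ref.mature_ids
    raw = rng.lognormal(config.abundance_log_mean, config.abundance_log_sd, len(mature_ids))
    cell = pd.Series(raw / raw.sum(), index=mature_ids)
    e = _export_propensities(config, rng, mature_ids)
    ev_raw = cell * np.power(2.0, e)
    ev = ev_raw / ev_raw.sum()
    truth = GroundTruth(cell_props=cell, ev_props=ev, e=e, spike=config.spike)
    if config.spike is not None:
        spike_id = config.spike.mirna_id or mature_ids[0]
        if spike_id not in cell.index:
            raise KeyError(f"spike miRNA {spike_id!r} not in reference")
        truth.spike = replace(config.spike, mirna_id=spike_id)
        truth.cell_props_spiked = _spiked_props(cell, spike_id, config.spike.cell_fraction)
        truth.ev_props_spiked = _spiked_props(ev, spike_id, config.spike.ev_fraction)
    return truth


def _condition_props(truth: GroundTruth) -> dict[str, dict[str, pd.Series]]:
    conditions = {"nt": {"cell": truth.cell_props, "EV": truth.ev_props}}
    if truth.cell_props_spiked is not None:
        conditions["tf"] = {"cell": truth.cell_props_spiked, "EV": truth.ev_props_spiked}
    return conditions


def simulate_count_tables(
    config: SimulationConfig, ref: HairpinReference | None = None
) -> tuple[CountTable, dict[str, tuple[str, str]], GroundTruth]:
    """Multinomial read counts per library, skipping read-level simulation.

    Returns the count table (libraries cell_nt, EV_nt and, with a spike,
    cell_tf, EV_tf), the condition -> (cell, EV) pairing and the ground
    truth. This is the fast path for testing normalization and export
    statistics at full library depth.
    """
    rng = config.rng()
    if ref is None:
        ref = simulate_reference(config, rng)
    truth = _truth(config, ref, rng)
    cols = {}
    pairing: dict[str, tuple[str, str]] = {}
    for cond, comps in _condition_props(truth).items():
        for comp, props in comps.items():
            label = f"{comp}_{cond}"
            cols[label] = rng.multinomial(config.reads_per_library, props.values).astype(float)
        pairing[cond] = (f"cell_{cond}", f"EV_{cond}")
    counts = pd.DataFrame(cols, index=truth.mature_ids)
    return CountTable.from_counts(counts), pairing, truth


def _mutate(read: bytearray, positions: np.ndarray, rng: np.random.Generator) -> None:
    for p in positions:
        old = read[p]
        choices = [b for b in _BASES if b != old]
        read[p] = int(rng.choice(choices))


def _reads_for_mirna(
    hp: Hairpin,
    arm: MatureArm,
    n_reads: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    label: str,
    start_index: int,
) -> tuple[list[Read], list[tuple]]:
    """Sample one miRNA's reads over isomiR classes with errors + adapter."""
    classes = list(config.isomir_offsets.items())
    probs = np.array([p for _, p in classes])
    class_counts = rng.multinomial(n_reads, probs / probs.sum())
    reads: list[Read] = []
    records: list[tuple] = []
    idx = start_index
    for ((o5, o3), _), n_class in zip(classes, class_counts):
        if n_class == 0:
            continue
        s0 = arm.start - 1 + o5
        e0 = arm.end + o3
        if s0 < 0 or e0 > len(hp.sequence) or e0 - s0 < 1:
            # offset walks off the hairpin: emit canonical instead
            s0, e0, o5, o3 = arm.start - 1, arm.end, 0, 0
        insert = hp.sequence[s0:e0]
        template = (insert + config.adapter)[: config.read_length]
        L = len(template)
        if config.error_rate > 0:
            p_any = 1.0 - (1.0 - config.error_rate) ** L
            k_err = rng.binomial(n_class, p_any)
        else:
            k_err = 0
        for _ in range(n_class - k_err):
            reads.append(Read(f"{label}:{idx:07d}", template))
            records.append((f"{label}:{idx:07d}", arm.mature_id, o5, o3, 0, 0))
            idx += 1
        for _ in range(k_err):
            n_err = 1 + rng.binomial(L - 1, config.error_rate)
            pos = rng.choice(L, size=min(n_err, L), replace=False)
            buf = bytearray(template.encode())
            _mutate(buf, pos, rng)
            in_insert = int((pos < len(insert)).sum())
            reads.append(Read(f"{label}:{idx:07d}", buf.decode()))
            records.append(
                (f"{label}:{idx:07d}", arm.mature_id, o5, o3, in_insert, len(pos))
            )
            idx += 1
    return reads, records


def simulate_libraries(
    config: SimulationConfig, ref: HairpinReference | None = None
) -> tuple[dict[str, ReadSet], dict[str, tuple[str, str]], GroundTruth]:
    """Full read-level simulation of the cell/EV (x condition) libraries.

    Read counts per miRNA are multinomial draws from each compartment's
    proportion vector; each read carries an isomiR end-offset class,
    possible substitution errors and the 3' adapter, truncated to the
    configured read length. Per-read source records land in
    ``truth.read_records[label]`` (read_id, mature_id, offset5, offset3,
    errors_in_insert, errors_total).
    """
    rng = config.rng()
    if ref is None:
        ref = simulate_reference(config, rng)
    truth = _truth(config, ref, rng)
    arms = {arm.mature_id: (hp, arm) for hp in ref for arm in hp.matures}
    readsets: dict[str, ReadSet] = {}
    pairing: dict[str, tuple[str, str]] = {}
    for cond, comps in _condition_props(truth).items():
        pairing[cond] = (f"cell_{cond}", f"EV_{cond}")
        for comp, props in comps.items():
            label = f"{comp}_{cond}"
            counts = rng.multinomial(config.reads_per_library, props.values)
            all_reads: list[Read] = []
            all_records: list[tuple] = []
            for mid, n_reads in zip(props.index, counts):
                if n_reads == 0:
                    continue
                hp, arm = arms[mid]
                reads, records = _reads_for_mirna(
                    hp, arm, int(n_reads), config, rng, label, len(all_reads)
                )
                all_reads.extend(reads)
                all_records.extend(records)
            readsets[label] = ReadSet(tuple(all_reads), comp, cond)
            truth.read_records[label] = pd.DataFrame(
                all_records,
                columns=[
                    "read_id",
                    "mature_id",
                    "offset5",
                    "offset3",
                    "errors_in_insert",
                    "errors_total",
                ],
            )
    return readsets, pairing, truth


def simulate_ct_table(
    truth: GroundTruth,
    noise_sd: float = 0.2,
    reference_mirna: str | None = None,
    n_replicates: int = 3,
    baseline: float = 15.0,
    condition: str = "nt",
    mirnas: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> CtTable:
    """Derive a triplicate Ct table from the true abundances.

    Ct = baseline - log2(abundance) + Gaussian noise per replicate well;
    zero-abundance miRNAs yield missing wells (no amplification). The
    reference miRNA defaults to the abundant miRNA with export ratio
    closest to 1 — the usual normalizer choice.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if condition == "tf" and truth.cell_props_spiked is not None:
        comps = {"cell": truth.cell_props_spiked, "EV": truth.ev_props_spiked}
    else:
        comps = {"cell": truth.cell_props, "EV": truth.ev_props}
    if reference_mirna is None:
        ratio = truth.true_log2_ratio(condition)
        abundant = truth.cell_props[truth.cell_props >= truth.cell_props.quantile(0.75)]
        reference_mirna = (ratio.loc[abundant.index].abs()).idxmin()
    selected = list(mirnas) if mirnas is not None else list(truth.mature_ids)
    if reference_mirna not in selected:
        selected.append(reference_mirna)
    rows = []
    for comp, props in comps.items():
        sample = f"{comp}_{condition}"
        for mid in selected:
            p = props.get(mid, 0.0)
            if p <= 0:
                continue  # undetermined wells are absent
            base_ct = baseline - math.log2(p)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": sample,
                        "mirna": mid,
                        "replicate": rep,
                        "ct": base_ct + rng.normal(0.0, noise_sd),
                    }
                )
    return CtTable(pd.DataFrame(rows), reference_mirna)


def simulate_dataset_panel(
    truth: GroundTruth,
    n_datasets: int = 8,
    platforms: Sequence[Platform] | None = None,
    rank_noise: float = 1.0,
    dropout: float = 0.2,
    condition: str = "nt",
    rng: np.random.Generator | None = None,
) -> list[DatasetMeasure]:
    """Emulate public datasets measuring the same export profile.

    Each dataset perturbs the true log2 export ratios with Gaussian noise
    of sd ``rank_noise`` and loses miRNAs to detection dropout; the
    expected blank fraction equals ``dropout``, with low-abundance miRNAs
    dropping out preferentially (detection probability decreases linearly
    with the miRNA's abundance quantile). Ratio platforms report EV:cell
    ratios, qPCR arrays report dCt — the same quantity on the log2 scale.
    """
    if n_datasets < 2:
        raise ValueError("n_datasets must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(0)
    if platforms is None:
        cycle: list[Platform] = ["sequencing", "microarray", "qpcr_array"]
        platforms = [cycle[i % 3] for i in range(n_datasets)]
    true_log2 = truth.true_log2_ratio(condition)
    abundance = np.maximum(truth.cell_props.values, truth.ev_props.values)
    # abundance quantile from the top: most abundant -> ~0, rarest -> ~1
    order = np.argsort(np.argsort(-abundance))
    q = order / max(len(abundance) - 1, 1)
    p_detect = np.clip(1.0 - 2.0 * dropout * q, 0.0, 1.0)
    out = []
    for i in range(n_datasets):
        noisy = true_log2.values + rng.normal(0.0, rank_noise, len(true_log2))
        detected = rng.random(len(true_log2)) < p_detect
        detected &= np.isfinite(true_log2.values)
        platform = platforms[i]
        if platform == "qpcr_array":
            scores = noisy  # dCt = log2(EV/cell) at efficiency 2
        else:
            scores = np.power(2.0, noisy)
        values = np.where(detected, scores, np.nan)
        out.append(
            DatasetMeasure(
                dataset_id=f"ds{i + 1:02d}_{platform}",
                platform=platform,
                scores=pd.Series(values, index=true_log2.index),
            )
        )
    return out
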