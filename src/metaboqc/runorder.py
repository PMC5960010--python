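"""Injection-sequence design and validation.

A well-designed untargeted-metabolomics batch opens with a system blank
and a suitability standard, conditions the platform with repeated
pooled-QC injections (their data are later discarded), brackets the
biological block with pairs of pooled QCs, interleaves a pooled QC every
few biological samples so drift can be modelled, spreads a handful of
long-term-reference injections across the run, and closes with trailing
QCs, a carryover process blank and a final suitability check.  The
validator re-checks any sequence — designed here or imported from a
worklist — against those placement rules.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .core_matrix import SampleType

__all__ = [
    "RunOrderSpec",
    "RunOrderEntry",
    "RunOrder",
    "RuleResult",
    "design_run_order",
    "design_study",
    "validate_run_order",
]

#: Types that count as re-conditioning injections after a blank.
_QC_LIKE = {SampleType.POOLED_QC, SampleType.CONDITIONING_QC}


@dataclasses.dataclass(frozen=True)
class RunOrderSpec:
    """Placement rules for one analytical batch.

    Defaults follow common practice for LC-MS untargeted assays: eight
    conditioning injections, lead/trail pooled-QC pairs, a pooled QC
    every fifth biological sample (never more than ten apart), at least
    five pooled QCs per batch (eight when a nonlinear drift model is
    planned), three reference (LTR/SRM) injections, and four
    re-conditioning QCs after any mid-run blank.
    """

    n_conditioning: int = 8
    n_lead_qc: int = 2
    n_trail_qc: int = 2
    qc_interval: int = 5
    max_qc_interval: int = 10
    min_qc_per_batch: int = 5
    min_qc_nonlinear: int = 8
    n_reference: int = 3
    reconditioning_after_blank: int = 4
    msms_block: bool = False
    msms_block_size: int = 3
    max_injections_per_vial: int = 3

    def __post_init__(self) -> None:
        for name in (
            "n_conditioning", "n_lead_qc", "n_trail_qc", "qc_interval",
            "max_qc_interval", "min_qc_per_batch", "min_qc_nonlinear",
            "reconditioning_after_blank", "max_injections_per_vial",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_reference < 0:
            raise ValueError("n_reference must be >= 0")
        if self.qc_interval > self.max_qc_interval:
            raise ValueError("qc_interval must be <= max_qc_interval")


@dataclasses.dataclass(frozen=True)
class RunOrderEntry:
    position: int
    sample_type: SampleType
    sample_id: str
    batch: int
    vial_id: str | None = None


@dataclasses.dataclass
class RunOrder:
    entries: list[RunOrderEntry]

    def __post_init__(self) -> None:
        positions = [e.position for e in self.entries]
        start = positions[0] if positions else 1
        if start < 1 or positions != list(range(start, start + len(positions))):
            raise ValueError("positions must be consecutive positive integers")

    @property
    def batch_ids(self) -> list[int]:
        out: list[int] = []
        for e in self.entries:
            if not out or out[-1] != e.batch:
                out.append(e.batch)
        return out

    def of_type(self, *types: SampleType) -> list[RunOrderEntry]:
        wanted = set(types)
        return [e for e in self.entries if e.sample_type in wanted]

    def to_rows(self) -> list[dict]:
        return [
            {
                "position": e.position,
                "sample_type": e.sample_type.value,
                "sample_id": e.sample_id,
                "batch": e.batch,
                "vial_id": e.vial_id or "",
            }
            for e in self.entries
        ]


@dataclasses.dataclass(frozen=True)
class RuleResult:
    rule: str
    passed: bool
    positions: tuple[int, ...] = ()
    message: str = ""


def design_run_order(
    n_biological: int,
    spec: RunOrderSpec | None = None,
    seed: int | None = None,
    *,
    batch: int = 1,
    start_position: int = 1,
    biological_ids: Sequence[str] | None = None,
    nonlinear_correction: bool = False,
) -> RunOrder:
    """Design a single-batch injection sequence.

    The biological samples are randomised by ``seed``; the QC/blank
    scaffold positions are deterministic.  Reference (LTR) injections
    are placed at even thirds of the biological block.  Pooled-QC vials
    are rotated with at most ``spec.max_injections_per_vial`` injections
    each.
    """
    if n_biological < 1:
        raise ValueError("n_biological must be >= 1")
    spec = spec or RunOrderSpec()
    rng = np.random.default_rng(seed)

    bio_ids = list(
        biological_ids
        if biological_ids is not None
        else [f"bio_{k:04d}" for k in range(1, n_biological + 1)]
    )
    if len(bio_ids) != n_biological:
        raise ValueError("biological_ids length must equal n_biological")
    bio_ids = [bio_ids[k] for k in rng.permutation(n_biological)]

    b = batch
    seq: list[tuple[SampleType, str]] = []
    counter = {"qc": 0, "cond": 0, "blank": 0, "ref": 0, "suit": 0}

    def add(stype: SampleType, label: str) -> None:
        seq.append((stype, label))

    def next_id(kind: str, stype: SampleType) -> str:
        counter[kind] += 1
        return f"{stype.value}_b{b}_{counter[kind]:02d}"

    add(SampleType.SYSTEM_BLANK, f"system_blank_b{b}")
    add(SampleType.SUITABILITY, f"suitability_b{b}_start")
    # conditioning block with a process blank midway (clean measurement of
    # systematic contamination); the blank is followed by the remaining
    # conditioning QCs, which re-condition before any biological sample
    half = spec.n_conditioning // 2
    for _ in range(half):
        add(SampleType.CONDITIONING_QC, next_id("cond", SampleType.CONDITIONING_QC))
    add(SampleType.PROCESS_BLANK, f"process_blank_b{b}_mid")
    for _ in range(spec.n_conditioning - half):
        add(SampleType.CONDITIONING_QC, next_id("cond", SampleType.CONDITIONING_QC))
    for _ in range(spec.n_lead_qc):
        add(SampleType.POOLED_QC, next_id("qc", SampleType.POOLED_QC))

    # reference injections after even thirds of the biological block
    ref_after = [
        max(1, round((r + 1) * n_biological / (spec.n_reference + 1)))
        for r in range(spec.n_reference)
    ]

    # interior pooled QCs: every qc_interval-th sample, densified when
    # that alone would leave the batch short of its pooled-QC floor
    min_total = spec.min_qc_nonlinear if nonlinear_correction else spec.min_qc_per_batch
    interior = {k for k in range(spec.qc_interval, n_biological, spec.qc_interval)}
    needed = min_total - spec.n_lead_qc - spec.n_trail_qc
    if len(interior) < needed:
        interior |= {
            min(max(1, round(i * n_biological / (needed + 1))), max(1, n_biological - 1))
            for i in range(1, needed + 1)
        }

    for k, bio in enumerate(bio_ids, start=1):
        add(SampleType.BIOLOGICAL, bio)
        for _ in range(ref_after.count(k)):
            counter["ref"] += 1
            add(SampleType.LTR, f"ltr_b{b}_{counter['ref']:02d}")
        if k in interior:
            add(SampleType.POOLED_QC, next_id("qc", SampleType.POOLED_QC))

    for _ in range(spec.n_trail_qc):
        add(SampleType.POOLED_QC, next_id("qc", SampleType.POOLED_QC))
    add(SampleType.PROCESS_BLANK, f"process_blank_b{b}_end")
    if spec.msms_block:
        for _ in range(spec.msms_block_size):
            add(SampleType.POOLED_QC, next_id("qc", SampleType.POOLED_QC))
    add(SampleType.SUITABILITY, f"suitability_b{b}_end")

    # rotate pooled-QC vials, max_injections_per_vial injections per vial
    entries: list[RunOrderEntry] = []
    qc_count = 0
    for offset, (stype, sid) in enumerate(seq):
        vial = None
        if stype in (SampleType.POOLED_QC, SampleType.CONDITIONING_QC):
            vial = f"qc_vial_{qc_count // spec.max_injections_per_vial + 1:02d}"
            qc_count += 1
        entries.append(
            RunOrderEntry(
                position=start_position + offset,
                sample_type=stype,
                sample_id=sid,
                batch=b,
                vial_id=vial,
            )
        )
    return RunOrder(entries)


def design_study(
    n_biological: int,
    n_batches: int,
    spec: RunOrderSpec | None = None,
    seed: int | None = None,
) -> RunOrder:
    """Multi-batch design: biological samples split evenly across batches."""
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    rng = np.random.default_rng(seed)
    all_ids = [f"bio_{k:04d}" for k in rng.permutation(np.arange(1, n_biological + 1))]
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n_biological), n_batches)]
    if min(sizes) < 1:
        raise ValueError("each batch needs at least one biological sample")
    entries: list[RunOrderEntry] = []
    pos = 1
    start = 0
    for b, size in enumerate(sizes, start=1):
        batch_order = design_run_order(
            size,
            spec,
            seed=None if seed is None else seed + b,
            batch=b,
            start_position=pos,
            biological_ids=all_ids[start : start + size],
        )
        entries.extend(batch_order.entries)
        pos += len(batch_order.entries)
        start += size
    return RunOrder(entries)


def validate_run_order(
    order: RunOrder,
    spec: RunOrderSpec | None = None,
    *,
    nonlinear_correction: bool = False,
) -> list[RuleResult]:
    """Check an injection sequence against the placement rules.

    Returns one :class:`RuleResult` per rule; a sequence passes when
    every result does.  Rules: bounded biological gap between pooled
    QCs, minimum pooled QCs per batch, lead/trail QC bracketing of the
    biological block, no biological sample directly after a blank, and
    sufficient re-conditioning QCs between a mid-run blank and the next
    biological sample.
    """
    if not order.entries:
        raise ValueError("run order is empty")
    spec = spec or RunOrderSpec()
    results: list[RuleResult] = []

    for b in order.batch_ids:
        batch_entries = [e for e in order.entries if e.batch == b]
        results.extend(_validate_batch(batch_entries, spec, b, nonlinear_correction))
    return results


def _validate_batch(
    entries: list[RunOrderEntry],
    spec: RunOrderSpec,
    batch: int,
    nonlinear: bool,
) -> list[RuleResult]:
    res: list[RuleResult] = []
    types = [e.sample_type for e in entries]
    pos = [e.position for e in entries]

    qc_pos = [p for p, t in zip(pos, types) if t is SampleType.POOLED_QC]
    bio_pos = [p for p, t in zip(pos, types) if t is SampleType.BIOLOGICAL]

    # bounded biological gap between consecutive pooled QCs
    bad_gaps: list[int] = []
    if bio_pos:
        segments: list[list[int]] = []
        current: list[int] = []
        for p, t in zip(pos, types):
            if t is SampleType.POOLED_QC:
                segments.append(current)
                current = []
            elif t is SampleType.BIOLOGICAL:
                current.append(p)
        segments.append(current)
        for seg in segments:
            if len(seg) > spec.max_qc_interval:
                bad_gaps.extend(seg)
    res.append(
        RuleResult(
            rule=f"batch {batch}: <= {spec.max_qc_interval} biological samples "
            f"between pooled QCs",
            passed=not bad_gaps,
            positions=tuple(bad_gaps),
            message="" if not bad_gaps else
            f"{len(bad_gaps)} biological injections in an unbracketed stretch",
        )
    )

    min_qc = spec.min_qc_nonlinear if nonlinear else spec.min_qc_per_batch
    res.append(
        RuleResult(
            rule=f"batch {batch}: >= {min_qc} pooled QCs"
            + (" (nonlinear correction planned)" if nonlinear else ""),
            passed=len(qc_pos) >= min_qc,
            message=f"found {len(qc_pos)} pooled QCs",
        )
    )

    if bio_pos:
        first_bio, last_bio = min(bio_pos), max(bio_pos)
        n_before = sum(1 for p in qc_pos if p < first_bio)
        n_after = sum(1 for p in qc_pos if p > last_bio)
        res.append(
            RuleResult(
                rule=f"batch {batch}: >= {spec.n_lead_qc} pooled QCs before first "
                f"biological sample",
                passed=n_before >= spec.n_lead_qc,
                message=f"found {n_before}",
            )
        )
        res.append(
            RuleResult(
                rule=f"batch {batch}: >= {spec.n_trail_qc} pooled QCs after last "
                f"biological sample",
                passed=n_after >= spec.n_trail_qc,
                message=f"found {n_after}",
            )
        )

    # no biological sample directly after a blank
    offenders = [
        entries[k + 1].position
        for k in range(len(entries) - 1)
        if types[k] in (SampleType.PROCESS_BLANK, SampleType.SYSTEM_BLANK)
        and types[k + 1] is SampleType.BIOLOGICAL
    ]
    res.append(
        RuleResult(
            rule=f"batch {batch}: no biological sample directly after a blank",
            passed=not offenders,
            positions=tuple(offenders),
        )
    )

    # re-conditioning after a mid-run blank: count QC-like injections
    # between each blank and the next biological sample
    weak: list[int] = []
    for k, t in enumerate(types):
        if t not in (SampleType.PROCESS_BLANK, SampleType.SYSTEM_BLANK):
            continue
        n_qc_between = 0
        for t2 in types[k + 1:]:
            if t2 is SampleType.BIOLOGICAL:
                if n_qc_between < spec.reconditioning_after_blank:
                    weak.append(entries[k].position)
                break
            if t2 in _QC_LIKE:
                n_qc_between += 1
    res.append(
        RuleResult(
            rule=f"batch {batch}: >= {spec.reconditioning_after_blank} QC "
            f"injections between a blank and the next biological sample",
            passed=not weak,
            positions=tuple(weak),
        )
    )
    return res
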