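"""Allele harmonization and instrument-validity filtering.

Two-sample MR requires the exposure and outcome effects of each variant to
be expressed for the same effect allele. :func:`harmonize` aligns the two
datasets, flipping the outcome effect sign where the datasets report
opposite alleles. :func:`filter_instruments` applies the instrument
conditions (genome-wide-significant exposure association, no outcome
association) and :func:`ld_prune` enforces pairwise independence through
greedy r²-within-window pruning.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .io import SummaryDataset

logger = logging.getLogger("ivmr")

PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A variant's exposure and outcome effects on a shared effect allele."""

    variant_id: str
    chromosome: str
    position_bp: int
    beta_exposure: float
    se_exposure: float
    p_exposure: float
    beta_outcome: float
    se_outcome: float
    p_outcome: float
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(f"{self.variant_id}: standard errors must be positive")


@dataclass(frozen=True)
class SelectionConfig:
    """Instrument-selection thresholds.

    Defaults implement the selection used for the IL-18/T2DM instruments:
    exposure significance P < 5e-8, outcome independence P > 0.05, LD
    pruning at r² >= 0.1 among pairs within a 500 kb window. Palindromic
    (A/T, C/G) variants are excluded by default because strand cannot be
    resolved without allele frequencies. ``strict_missing_ld`` treats an
    unknown in-window r² as above threshold (prune); set it False to treat
    missing r² as 0.
    """

    p_exposure_max: float = 5e-8
    p_outcome_min: float = 0.05
    r2_max: float = 0.1
    window_bp: int = 500_000
    palindromic_policy: str = "exclude"
    strict_missing_ld: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.p_exposure_max < 1:
            raise ValueError("p_exposure_max must lie in (0, 1)")
        if not 0 < self.p_outcome_min < 1:
            raise ValueError("p_outcome_min must lie in (0, 1)")
        if not 0 <= self.r2_max <= 1:
            raise ValueError("r2_max must lie in [0, 1]")
        if self.window_bp < 0:
            raise ValueError("window_bp must be non-negative")
        if self.palindromic_policy not in ("exclude", "keep"):
            raise ValueError("palindromic_policy must be 'exclude' or 'keep'")


def _is_palindromic(ea: str | None, oa: str | None) -> bool:
    return ea is not None and oa is not None and (ea, oa) in PALINDROMIC_PAIRS


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindromic_policy: str = "exclude",
) -> list[HarmonizedInstrument]:
    """Join exposure and outcome records on variant_id and align alleles.

    For each shared variant: if the outcome's effect allele equals the
    exposure's, effects are combined as-is; if the outcome reports the
    opposite allele, its beta is negated and the instrument marked
    ``flipped``; when neither dataset carries allele labels the records are
    joined as-is (the caller asserts pre-harmonization). Variants whose
    allele pairs are neither identical nor a flip are dropped with a logged
    reason, as are palindromic variants under ``palindromic_policy="exclude"``.

    Raises ``ValueError`` when the datasets share no variant.
    """
    if palindromic_policy not in ("exclude", "keep"):
        raise ValueError("palindromic_policy must be 'exclude' or 'keep'")
    out_by_id = {r.variant_id: r for r in outcome.records}
    shared = [r for r in exposure.records if r.variant_id in out_by_id]
    if not shared:
        raise ValueError("exposure and outcome datasets share no variant_id")

    instruments: list[HarmonizedInstrument] = []
    for e in shared:
        o = out_by_id[e.variant_id]
        if palindromic_policy == "exclude" and (
            _is_palindromic(e.effect_allele, e.other_allele)
            or _is_palindromic(o.effect_allele, o.other_allele)
        ):
            logger.info("%s dropped: palindromic allele pair", e.variant_id)
            continue

        flipped = False
        beta_outcome = o.beta
        if e.effect_allele is not None and o.effect_allele is not None:
            same = o.effect_allele == e.effect_allele and (
                o.other_allele is None
                or e.other_allele is None
                or o.other_allele == e.other_allele
            )
            flip = o.effect_allele == e.other_allele and (
                o.other_allele is None or o.other_allele == e.effect_allele
            )
            if same:
                pass
            elif flip:
                beta_outcome = -o.beta
                flipped = True
            else:
                logger.info(
                    "%s dropped: allele mismatch (%s/%s vs %s/%s)",
                    e.variant_id,
                    e.effect_allele,
                    e.other_allele,
                    o.effect_allele,
                    o.other_allele,
                )
                continue
        # one or both sides without allele labels: joined as-is

        instruments.append(
            HarmonizedInstrument(
                variant_id=e.variant_id,
                chromosome=e.chromosome,
                position_bp=e.position_bp,
                beta_exposure=e.beta,
                se_exposure=e.se,
                p_exposure=e.pvalue,
                beta_outcome=beta_outcome,
                se_outcome=o.se,
                p_outcome=o.pvalue,
                flipped=flipped,
            )
        )
    return instruments


def filter_instruments(
    instruments: Sequence[HarmonizedInstrument],
    config: SelectionConfig | None = None,
) -> list[HarmonizedInstrument]:
    """Retain instruments strongly associated with the exposure and not the outcome.

    Keeps exactly those with ``p_exposure < p_exposure_max``,
    ``beta_exposure != 0`` and ``p_outcome > p_outcome_min`` (strict
    inequalities), preserving order. Idempotent.
    """
    config = config or SelectionConfig()
    kept: list[HarmonizedInstrument] = []
    for inst in instruments:
        if inst.p_exposure >= config.p_exposure_max:
            logger.info("%s dropped: p_exposure %.3g >= %.3g",
                        inst.variant_id, inst.p_exposure, config.p_exposure_max)
        elif inst.beta_exposure == 0:
            logger.info("%s dropped: zero exposure effect", inst.variant_id)
        elif inst.p_outcome <= config.p_outcome_min:
            logger.info("%s dropped: p_outcome %.3g <= %.3g (outcome-associated)",
                        inst.variant_id, inst.p_outcome, config.p_outcome_min)
        else:
            kept.append(inst)
    if not kept:
        logger.warning("filter_instruments: no instrument survived")
    return kept


LdLookup = Mapping[tuple[str, str], float] | Callable[[str, str], float | None]


def _ld_getter(ld_r2: LdLookup) -> Callable[[str, str], float | None]:
    if callable(ld_r2):
        return ld_r2

    def get(a: str, b: str) -> float | None:
        if (a, b) in ld_r2:
            return ld_r2[(a, b)]
        return ld_r2.get((b, a))

    return get


def ld_prune(
    instruments: Sequence[HarmonizedInstrument],
    ld_r2: LdLookup,
    config: SelectionConfig | None = None,
) -> list[HarmonizedInstrument]:
    """Greedy LD pruning by exposure p-value rank.

    Instruments are ranked by ascending ``p_exposure`` (ties broken by
    variant_id); each is kept unless it lies within ``window_bp`` of an
    already-kept instrument on the same chromosome AND has r² >= ``r2_max``
    with it. An in-window pair with no r² available is pruned under
    ``strict_missing_ld`` (default) or kept otherwise. Output follows rank
    order.
    """
    config = config or SelectionConfig()
    get_r2 = _ld_getter(ld_r2)
    ranked = sorted(instruments, key=lambda i: (i.p_exposure, i.variant_id))
    kept: list[HarmonizedInstrument] = []
    for inst in ranked:
        pruned = False
        for anchor in kept:
            if anchor.chromosome != inst.chromosome:
                continue
            if abs(anchor.position_bp - inst.position_bp) > config.window_bp:
                continue
            r2 = get_r2(anchor.variant_id, inst.variant_id)
            if r2 is None:
                if config.strict_missing_ld:
                    logger.info(
                        "%s pruned: no r2 with in-window %s (strict policy)",
                        inst.variant_id, anchor.variant_id,
                    )
                    pruned = True
                    break
                continue
            if not 0 <= r2 <= 1:
                raise ValueError(
                    f"r2 for ({anchor.variant_id}, {inst.variant_id}) outside [0, 1]: {r2}"
                )
            if r2 >= config.r2_max:
                logger.info(
                    "%s pruned: r2 %.3f with %s within %d bp",
                    inst.variant_id, r2, anchor.variant_id, config.window_bp,
                )
                pruned = True
                break
        if not pruned:
            kept.append(inst)
    return kept


def read_ld_table(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a three-column (variant_id_1, variant_id_2, r2) delimited file."""
    path = Path(path)
    table: dict[tuple[str, str], float] = {}
    with open(path, newline="") as fh:
        sample = fh.readline()
        sep = "," if ("," in sample and "\t" not in sample) else "\t"
        fh.seek(0)
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader)
        rows = [header] if header and _is_float(header[-1]) else []
        rows.extend(reader)
    for row in rows:
        if len(row) < 3:
            continue
        r2 = float(row[2])
        if not 0 <= r2 <= 1:
            raise ValueError(f"r2 for ({row[0]}, {row[1]}) outside [0, 1]: {r2}")
        table[(row[0], row[1])] = r2
    return table


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def flip_instrument(inst: HarmonizedInstrument) -> HarmonizedInstrument:
    """Re-express an instrument for the opposite effect allele (both betas negated)."""
    return replace(
        inst,
        beta_exposure=-inst.beta_exposure,
        beta_outcome=-inst.beta_outcome,
        flipped=not inst.flipped,
    )
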