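"""Replicate aggregation, ranking, hotspot selection and round reports.

Each variant is screened as many independent EVB tasks (replica ×
snapshot); this module reduces those task records to per-variant
summaries (mean/median/sd of ΔG‡ and ΔG₀), ranks variants by predicted
barrier, flags results that look too good to be true, and exports the
round as deterministic CSV/JSON files.

Flag semantics: a flag never changes a stored number, it only annotates.
``suspicious_drop`` marks a barrier more than ``drop_threshold`` below
the wild type — in a real campaign such a drop usually means the active
site was disrupted by the substitution rather than genuinely improved —
and ``no_barrier_fraction`` marks variants whose profiles frequently had
no transition state at all.
"""

from __future__ import annotations

import hashlib
import json
import math
import statistics
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .errors import InvalidInputError
from .variants import parse_variant

__all__ = [
    "VariantSummary",
    "aggregate",
    "rank_variants",
    "flag_suspicious",
    "select_hotspots",
    "export_round_report",
    "HotspotNotice",
]

#: default "too good to be true" barrier drop relative to WT, kcal/mol
DEFAULT_DROP_THRESHOLD = 5.0

#: flag variants when more than this fraction of records had no barrier
NO_BARRIER_FRACTION_LIMIT = 0.25


class HotspotNotice(UserWarning):
    """Non-fatal hotspot-selection event (skipped or short selection)."""


@dataclass(frozen=True)
class VariantSummary:
    variant: str
    n: int
    mean_dG_act: float
    median_dG_act: float
    sd_dG_act: float
    mean_dG_rxn: float
    sd_dG_rxn: float
    no_barrier_fraction: float = 0.0
    flags: frozenset = frozenset()

    def statistic(self, which: str) -> float:
        if which == "mean":
            return self.mean_dG_act
        if which == "median":
            return self.median_dG_act
        raise InvalidInputError(f"unknown statistic {which!r}")


def _moments(values: List[float]):
    n = len(values)
    if n == 0:
        return math.nan, math.nan, 0.0
    mean = statistics.fmean(values)
    median = statistics.median(values)
    sd = statistics.stdev(values) if n >= 2 else 0.0
    return mean, median, sd


def aggregate(results: Iterable[dict],
              statistic: str = "mean") -> List[VariantSummary]:
    """Per-variant summaries over successful task records.

    Records with a ``no_barrier`` marker count into the no-barrier
    fraction but are excluded from the moments; failed records are
    ignored.  A variant with zero successful records yields an ``n=0``
    summary carrying the ``low_n`` flag rather than an exception.
    Summaries are returned in variant-label order (deterministic in the
    input's record order).
    """
    if statistic not in ("mean", "median"):
        raise InvalidInputError(f"unknown statistic {statistic!r}")
    by_variant: Dict[str, dict] = {}
    for rec in results:
        v = rec["variant"]
        slot = by_variant.setdefault(
            v, {"act": [], "rxn": [], "no_barrier": 0, "total": 0}
        )
        if rec.get("status") == "failed":
            continue
        slot["total"] += 1
        if rec.get("no_barrier"):
            slot["no_barrier"] += 1
            continue
        act = rec.get("dG_act")
        if act is None or not math.isfinite(act):
            slot["no_barrier"] += 1
            continue
        slot["act"].append(float(act))
        rxn = rec.get("dG_rxn")
        if rxn is not None and math.isfinite(rxn):
            slot["rxn"].append(float(rxn))

    out = []
    for v in sorted(by_variant):
        slot = by_variant[v]
        mean_a, med_a, sd_a = _moments(slot["act"])
        mean_r, _, sd_r = _moments(slot["rxn"])
        n = len(slot["act"])
        flags = set()
        if n <= 1:
            flags.add("low_n")
        nb_frac = (slot["no_barrier"] / slot["total"]
                   if slot["total"] else 0.0)
        out.append(VariantSummary(
            variant=v, n=n,
            mean_dG_act=mean_a, median_dG_act=med_a, sd_dG_act=sd_a,
            mean_dG_rxn=mean_r, sd_dG_rxn=sd_r,
            no_barrier_fraction=nb_frac, flags=frozenset(flags),
        ))
    return out


def rank_variants(summaries: Sequence[VariantSummary],
                  statistic: str = "mean") -> List[VariantSummary]:
    """Ascending by the chosen ΔG‡ statistic; ties by sd then label.

    Variants without an estimate (n = 0) sort last.
    """
    if not summaries:
        raise InvalidInputError("rank_variants needs at least one summary")

    def key(s: VariantSummary):
        stat = s.statistic(statistic)
        return (not math.isfinite(stat),
                stat if math.isfinite(stat) else 0.0,
                s.sd_dG_act, s.variant)

    return sorted(summaries, key=key)


def flag_suspicious(
    summaries: Sequence[VariantSummary],
    wt_summary: VariantSummary,
    drop_threshold: float = DEFAULT_DROP_THRESHOLD,
    statistic: str = "mean",
) -> List[VariantSummary]:
    """Annotate summaries; numeric fields are never altered.

    ``suspicious_drop``: ΔG‡ statistic more than ``drop_threshold`` below
    the wild type's.  ``no_barrier_fraction``: more than 25% of the
    variant's records had no transition state.
    """
    wt_stat = wt_summary.statistic(statistic)
    out = []
    for s in summaries:
        flags = set(s.flags)
        stat = s.statistic(statistic)
        if math.isfinite(stat) and stat < wt_stat - drop_threshold:
            flags.add("suspicious_drop")
        if s.no_barrier_fraction > NO_BARRIER_FRACTION_LIMIT:
            flags.add("no_barrier_fraction")
        out.append(replace(s, flags=frozenset(flags)))
    return out


def select_hotspots(
    alanine_summaries: Sequence[VariantSummary],
    k: int,
    wt_summary: Optional[VariantSummary] = None,
    statistic: str = "mean",
    drop_threshold: float = DEFAULT_DROP_THRESHOLD,
) -> List[int]:
    """Positions whose alanine variant ranks lowest in ΔG‡.

    Variants flagged suspicious (when a wild-type summary is supplied for
    comparison) are skipped with a notice and the next-ranked position is
    taken instead.  Asking for more positions than available returns all,
    with a warning.
    """
    if k == 0:
        return []
    summaries = [s for s in alanine_summaries if s.variant != "WT"]
    if wt_summary is not None:
        summaries = flag_suspicious(summaries, wt_summary,
                                    drop_threshold, statistic)
    ranked = rank_variants(summaries, statistic)
    positions: List[int] = []
    for s in ranked:
        if s.n == 0:
            continue
        if "suspicious_drop" in s.flags or "no_barrier_fraction" in s.flags:
            warnings.warn(
                f"{s.variant} skipped for hotspot selection "
                f"(flags: {sorted(s.flags)})", HotspotNotice,
            )
            continue
        v = parse_variant(s.variant)
        if len(v.substitutions) != 1:
            continue
        positions.append(v.substitutions[0].position)
        if len(positions) == k:
            return positions
    warnings.warn(
        f"only {len(positions)} selectable positions for k={k}",
        HotspotNotice,
    )
    return positions


def _summaries_frame(summaries: Sequence[VariantSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variant": s.variant, "n": s.n,
        "mean_dG_act": s.mean_dG_act, "median_dG_act": s.median_dG_act,
        "sd_dG_act": s.sd_dG_act, "mean_dG_rxn": s.mean_dG_rxn,
        "sd_dG_rxn": s.sd_dG_rxn,
        "no_barrier_fraction": s.no_barrier_fraction,
        "flags": "|".join(sorted(s.flags)),
    } for s in summaries])


_REPORT_COLUMNS = ["variant", "n", "mean_dG_act", "median_dG_act",
                   "sd_dG_act", "mean_dG_rxn", "sd_dG_rxn",
                   "no_barrier_fraction", "flags"]


def export_round_report(
    summaries: Sequence[VariantSummary],
    round_metadata: dict,
    out_dir,
    statistic: str = "mean",
    grouping: Optional[Sequence[int]] = None,
) -> Dict[str, Path]:
    """Write the round as ``report.csv`` (+ grouped table) + ``round.json``.

    ``grouping`` names two mutated positions; when given (or when every
    variant mutates the same ≥ 2 positions, in which case the two lowest
    are used) a second table groups variants by the residues chosen at
    those positions — the natural layout of a combinatorial round.  The
    JSON round record carries the metadata, the statistic used, and a
    content hash for round-over-round provenance.  Output is
    deterministic: identical inputs re-export byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = _summaries_frame(summaries)
    if len(df) == 0:
        df = pd.DataFrame(columns=_REPORT_COLUMNS)
    df = df[_REPORT_COLUMNS]
    csv_path = out_dir / "report.csv"
    df.to_csv(csv_path, index=False, float_format="%.6f")

    paths = {"report": csv_path}

    if grouping is None and len(df):
        pos_sets = {parse_variant(v).positions for v in df["variant"]
                    if v != "WT"}
        if len(pos_sets) == 1 and len(next(iter(pos_sets))) >= 2:
            grouping = sorted(next(iter(pos_sets)))[:2]
    if grouping is not None and len(df):
        p1, p2 = int(grouping[0]), int(grouping[1])

        def residue_at(label: str, pos: int) -> str:
            for sub in parse_variant(label).substitutions:
                if sub.position == pos:
                    return sub.new_aa
            return "wt"

        gdf = df.copy()
        gdf.insert(0, f"aa_{p1}", [residue_at(v, p1)
                                   for v in gdf["variant"]])
        gdf.insert(1, f"aa_{p2}", [residue_at(v, p2)
                                   for v in gdf["variant"]])
        gdf = gdf.sort_values(
            [f"aa_{p1}", f"aa_{p2}", "variant"]).reset_index(drop=True)
        gpath = out_dir / "report_grouped.csv"
        gdf.to_csv(gpath, index=False, float_format="%.6f")
        paths["grouped"] = gpath

    payload = {
        "round": round_metadata,
        "statistic": statistic,
        "n_variants": int(len(df)),
        "content_hash": hashlib.sha256(
            csv_path.read_bytes()).hexdigest(),
    }
    json_path = out_dir / "round.json"
    json_path.write_text(json.dumps(payload, sort_keys=True, indent=1)
                         + "\n")
    paths["round"] = json_path
    return paths
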