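"""Scoring pipeline output against synthetic ground truth.

Used to quantify how well each stage recovers what the generator actually
simulated: pooled route-strategy calls, departure dates (exact for known
dates, containment for windows), stopovers (time-overlap at a true stopover
station), and the QC filter's true/false-positive retention.
"""

from __future__ import annotations

import pandas as pd

from .model import DepartureEstimate, StrategyCall, Stopover
from .simulate import SimResult


def pooled_strategy_recovery(calls: list[StrategyCall], result: SimResult) -> dict:
    """Fraction of unambiguous-truth birds (true stopped vs true skipped
    routes) whose pooled classification matches; unknown calls count as
    misses. Ambiguous truths (e.g. Atlantic non-bay routes) are reported
    separately but not scored."""
    truth = result.truth_by_tag()
    call_of = {c.tag_id: c for c in calls}
    n_match = n_total = 0
    misses = []
    for tag, t in truth.items():
        if not t["unambiguous"]:
            continue
        n_total += 1
        c = call_of.get(tag)
        if c is not None and c.pooled == t["pooled"]:
            n_match += 1
        else:
            misses.append({"tag_id": tag, "true": t["pooled"],
                           "called": c.strategy if c else "not classified"})
    n_ambiguous = sum(1 for t in truth.values() if not t["unambiguous"])
    return {"n_scored": n_total, "n_match": n_match,
            "recovery": n_match / n_total if n_total else None,
            "n_ambiguous_truth": n_ambiguous, "misses": misses}


def departure_recovery(estimates: list[DepartureEstimate], result: SimResult) -> dict:
    """Known estimates must equal the true departure date; windows must
    contain it. Birds with no estimate are scored only if the generator gave
    them any detections away from the capture site (here: all birds)."""
    truth = result.truth_by_tag()
    est_of = {e.tag_id: e for e in estimates}
    n_ok = n_total = 0
    failures = []
    for tag, t in truth.items():
        true_date = pd.Timestamp(t["departure_date"]).date()
        n_total += 1
        e = est_of.get(tag)
        if e is None:
            failures.append({"tag_id": tag, "reason": "no estimate"})
        elif e.kind == "known":
            if e.known_date == true_date:
                n_ok += 1
            else:
                failures.append({"tag_id": tag, "reason":
                                 f"known {e.known_date} != true {true_date}"})
        else:
            if e.window_start <= true_date <= e.window_end:
                n_ok += 1
            else:
                failures.append({"tag_id": tag, "reason":
                                 f"window [{e.window_start}, {e.window_end}] "
                                 f"misses {true_date}"})
    return {"n_scored": n_total, "n_ok": n_ok,
            "recovery": n_ok / n_total if n_total else None, "failures": failures}


def stopover_recovery(stopovers: list[Stopover], result: SimResult) -> dict:
    """A true stopover is recovered when the same bird has a detected
    stopover that includes the true station and overlaps it in time."""
    by_tag: dict[str, list[Stopover]] = {}
    for s in stopovers:
        by_tag.setdefault(s.tag_id, []).append(s)
    n_ok = n_total = 0
    misses = []
    for t in result.truth:
        for ts in t["stopovers"]:
            n_total += 1
            t0, t1 = pd.Timestamp(ts["start"]), pd.Timestamp(ts["end"])
            hit = any(ts["station"] in s.stations and s.start <= t1 and s.end >= t0
                      for s in by_tag.get(t["tag_id"], []))
            if hit:
                n_ok += 1
            else:
                misses.append({"tag_id": t["tag_id"], "station": ts["station"]})
    return {"n_true": n_total, "n_recovered": n_ok,
            "recovery": n_ok / n_total if n_total else None, "misses": misses}


def qc_retention(valid: pd.DataFrame, result: SimResult) -> dict:
    """True-positive and false-positive retention of the QC filter."""
    det = result.dataset.detections
    flags = pd.Series(result.is_true_detection, index=det.index)
    kept = det.index.isin(valid.index)
    n_true = int(flags.sum())
    n_false = int((~flags).sum())
    tp_kept = int((flags & kept).sum())
    fp_kept = int((~flags & kept).sum())
    return {"n_true": n_true, "n_false": n_false,
            "tp_retention": tp_kept / n_true if n_true else None,
            "fp_retention": fp_kept / n_false if n_false else None}
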