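"""Aggregation of per-patch predictions into eplet-level scores.

A patch prediction concerns one residue of one antigen, but an eplet
exists on every antigen that carries it, and a composite eplet spans
several residues.  The aggregated scores are

* single eplet (one residue ``r``):  ``S_r`` = mean of ``pred(r, a)``
  over the antigens ``A_r`` carrying the eplet;
* composite eplet ``e``: per antigen, ``P_ae`` = max of ``pred(r, a)``
  over the eplet's solvent-accessible residues, then
  ``S_e`` = mean of ``P_ae`` over the carrying antigens ``A_e``.

An eplet is *confirmed* by a model when its aggregated score reaches
the threshold (>= 0.50 by default).  Antigens contributing no scored
residue are dropped from the average rather than counted as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

from .constants import EPLET_THRESHOLD
from .registry import EpletRecord


def score_single_eplet(preds: Mapping[str, float]) -> float:
    """Mean prediction over the antigens carrying a single-residue eplet."""
    if not preds:
        raise ValueError("no antigen predictions to aggregate")
    vals = list(preds.values())
    if any(not (0.0 <= v <= 1.0) for v in vals):
        raise ValueError("prediction scores must lie in [0, 1]")
    return float(sum(vals) / len(vals))


def score_composite_eplet(preds: Mapping[str, Mapping[object, float]]) -> float:
    """Max over eplet residues per antigen, then mean over antigens.

    ``preds`` maps antigen id to a map residue -> prediction score for
    the eplet's solvent-accessible residues on that antigen.  Antigens
    with an empty residue map are excluded (with a warning).
    """
    per_antigen: dict[str, float] = {}
    for antigen, residue_scores in preds.items():
        if not residue_scores:
            warnings.warn(
                f"antigen {antigen!r} has no scored eplet residue; "
                "excluded from aggregation",
                stacklevel=2,
            )
            continue
        per_antigen[antigen] = max(residue_scores.values())
    return score_single_eplet(per_antigen)


def confirm(score: float, threshold: float = EPLET_THRESHOLD) -> bool:
    """True when the aggregated score reaches the threshold (inclusive)."""
    if not (0.0 <= score <= 1.0):
        raise ValueError("score must lie in [0, 1]")
    return score >= threshold


@dataclass
class EpletScoreResult:
    """Aggregated per-model scores for one eplet."""

    eplet: EpletRecord
    scores: dict[str, float]  # model name -> S_r or S_e
    confirmed: dict[str, bool]
    n_antigens: int


def score_report(
    eplets: list[EpletRecord],
    patch_scores: Mapping[str, Mapping[str, Mapping[object, float]]],
    threshold: float = EPLET_THRESHOLD,
    sort_model: str | None = None,
):
    """Aggregate per-model patch scores into an eplet report table.

    Parameters
    ----------
    eplets:
        Registry records to score.
    patch_scores:
        ``model -> eplet name -> antigen -> residue -> pred`` nested
        mapping (for single eplets the residue level has one entry).
        Eplets absent from every model's map (no solvent-accessible
        residue could be patched) are listed as excluded.
    threshold:
        Confirmation threshold, inclusive.
    sort_model:
        Model whose score orders the rows (descending); defaults to the
        last model name.

    Returns
    -------
    (results, excluded):
        Scored :class:`EpletScoreResult` rows and names of unpatchable
        eplets.
    """
    models = list(patch_scores)
    if sort_model is None and models:
        sort_model = models[-1]
    results: list[EpletScoreResult] = []
    excluded: list[str] = []
    for rec in eplets:
        per_model: dict[str, float] = {}
        n_antigens = 0
        for model in models:
            preds = patch_scores[model].get(rec.name)
            if not preds or all(not v for v in preds.values()):
                continue
            per_model[model] = score_composite_eplet(
                {a: dict(r) for a, r in preds.items()}
            )
            n_antigens = max(
                n_antigens, sum(1 for r in preds.values() if r)
            )
        if not per_model:
            excluded.append(rec.name)
            continue
        results.append(
            EpletScoreResult(
                eplet=rec,
                scores=per_model,
                confirmed={m: confirm(s, threshold) for m, s in per_model.items()},
                n_antigens=n_antigens,
            )
        )
    if sort_model is not None:
        results.sort(key=lambda r: -r.scores.get(sort_model, -1.0))
    return results, excluded


def report_to_frame(results: list[EpletScoreResult], excluded: list[str] | None = None):
    """Tabular view of a score report (one row per eplet)."""
    import pandas as pd

    rows = []
    for r in results:
        row = {
            "eplet": r.eplet.name,
            "chain": r.eplet.chain,
            "composite": r.eplet.composite,
            "n_antigens": r.n_antigens,
        }
        for model, score in r.scores.items():
            row[f"score_{model}"] = score
            row[f"confirmed_{model}"] = r.confirmed[model]
        rows.append(row)
    df = pd.DataFrame(rows)
    if excluded:
        df.attrs["excluded"] = list(excluded)
    return df
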