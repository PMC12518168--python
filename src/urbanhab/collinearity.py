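"""Pairwise Pearson screening and priority-based variable retention.

Continuous layers are screened over the shared valid cells; pairs with
|r| >= threshold are resolved by dropping the lower member of a user-supplied
ecological priority ordering, which makes the published "retain ecologically
meaningful variables" step deterministic and auditable.  Categorical layers
(nominal data) bypass Pearson screening and are retained by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .raster_io import LayerStack

__all__ = ["CorrelationReport", "pearson_matrix", "select_variables"]


@dataclass
class CorrelationReport:
    names: list[str]
    matrix: pd.DataFrame
    threshold: float | None = None
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)

    def to_csv(self, matrix_path: str | Path, report_path: str | Path | None = None) -> None:
        self.matrix.to_csv(matrix_path)
        if report_path is not None:
            lines = [f"threshold: |r| >= {self.threshold}"]
            for a, b, r in self.flagged_pairs:
                lines.append(f"flagged: {a} ~ {b} (r = {r:+.3f})")
            for name, reason in self.dropped.items():
                lines.append(f"dropped: {name} — {reason}")
            lines.append("retained: " + ", ".join(self.retained))
            Path(report_path).write_text("\n".join(lines) + "\n")


def pearson_matrix(stack: LayerStack, sample_size: int | None = None,
                   seed: int | None = None) -> CorrelationReport:
    """Pearson r over shared valid cells for the continuous layers.

    With ``sample_size`` set, r is computed on a seeded random cell subsample.
    Constant layers get r = 0 against everything (with a warning).
    """
    names = stack.continuous_names
    if len(names) < 2:
        raise ValueError("need at least 2 continuous layers")
    mask = stack.shared_mask
    rows, cols = np.nonzero(mask)
    if rows.size < 3:
        raise ValueError(f"only {rows.size} shared valid cells; need at least 3")
    if sample_size is not None and sample_size < rows.size:
        rng = np.random.default_rng(seed)
        pick = rng.choice(rows.size, size=sample_size, replace=False)
        rows, cols = rows[pick], cols[pick]
    data = np.vstack([stack.grids[n].values[rows, cols] for n in names])
    constant = data.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"constant layer(s) {[n for n, c in zip(names, constant) if c]}: "
            "correlation set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    matrix = pd.DataFrame(r, index=names, columns=names)
    return CorrelationReport(list(names), matrix)


def select_variables(report: CorrelationReport, threshold: float = 0.8,
                     priority: Sequence[str] | None = None,
                     categorical: Sequence[str] = ()) -> CorrelationReport:
    """Resolve flagged pairs by dropping the lower-priority member.

    ``priority`` must list every continuous candidate exactly once, highest
    priority (most ecologically meaningful) first; by default the report's
    layer order is used.  Flagged pairs are visited in priority order and,
    whenever both members are still retained, the lower-priority one is
    dropped.  Categorical layers are appended to the retained list untouched.
    """
    names = report.names
    if priority is None:
        priority = list(names)
    if sorted(priority) != sorted(names):
        extra = set(priority) - set(names)
        missing = set(names) - set(priority)
        raise ValueError(
            f"priority must list every candidate exactly once "
            f"(unknown: {sorted(extra)}, missing: {sorted(missing)})")
    rank = {name: i for i, name in enumerate(priority)}
    r = report.matrix

    flagged = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if abs(r.loc[a, b]) >= threshold:
                hi, lo = sorted((a, b), key=rank.get)
                flagged.append((hi, lo, float(r.loc[a, b])))
    flagged.sort(key=lambda t: (rank[t[0]], rank[t[1]]))

    retained = set(names)
    dropped: dict[str, str] = {}
    for hi, lo, rv in flagged:
        if hi in retained and lo in retained:
            retained.discard(lo)
            dropped[lo] = f"|r|={abs(rv):.3f} >= {threshold} with higher-priority {hi}"

    kept = [n for n in priority if n in retained]
    # screened result must contain no flagged pair
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            assert abs(r.loc[a, b]) < threshold
    return CorrelationReport(
        names=list(names),
        matrix=report.matrix,
        threshold=threshold,
        flagged_pairs=flagged,
        retained=kept + [c for c in categorical if c not in kept],
        dropped=dropped,
    )
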