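"""Production summaries and flux-difference tables.

``summarize_production`` derives, for each strain row of a rates table, the
sum of product rates (1,3-PDO + glycerol, i.e. total DHAP drained into the
synthetic pathway), its fold-change versus a reference strain, the 1,3-PDO
ratio (q_PDO / sum) and the ratio's fold-change — the derived columns of a
production-comparison table.  ``flux_difference_table`` tabulates per-
reaction flux shifts between a reference and a knockout state, e.g. around
the DHAP branch point.

All arithmetic is done on unrounded values; display rounding (3 significant
digits for rates/sums/ratios, 2 decimals for folds) only happens in the
``display_*`` accessors and the TSV renderer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .fba import round_sig
from .model import FluxState


@dataclass
class SummaryRow:
    label: str
    mu: float
    q_pdo: float
    q_glycerol: float
    sum_products: float
    fold_vs_ref: float
    pdo_ratio: float
    ratio_fold_vs_ref: float

    def display(self) -> dict:
        return {
            "strain": self.label,
            "mu": round_sig(self.mu, 3),
            "q_pdo": round_sig(self.q_pdo, 3),
            "q_glycerol": round_sig(self.q_glycerol, 3),
            "sum_products": round_sig(self.sum_products, 3),
            "fold_vs_ref": round(self.fold_vs_ref, 2),
            "pdo_ratio": round_sig(self.pdo_ratio, 3),
            "ratio_fold_vs_ref": round(self.ratio_fold_vs_ref, 2),
        }


def summarize_production(rows: pd.DataFrame, reference_label: str) -> list:
    """Derive sum/ratio/fold columns from a rates table.

    ``rows`` needs columns strain, mu, q_pdo, q_glycerol (the TSV layout of
    :func:`pdoflux.io.read_rates_table`).  Folds are relative to
    ``reference_label``, whose own folds are exactly 1.  A reference with a
    zero product sum has no defined folds and raises.
    """
    required = {"strain", "mu", "q_pdo", "q_glycerol"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"rates table missing columns {sorted(missing)}")
    ref = rows[rows["strain"] == reference_label]
    if ref.empty:
        raise ValueError(f"reference strain {reference_label!r} not in table")
    ref = ref.iloc[0]
    sum_ref = float(ref["q_pdo"] + ref["q_glycerol"])
    if sum_ref == 0:
        raise ZeroDivisionError(
            f"reference strain {reference_label!r} has zero product sum; "
            f"fold columns are undefined"
        )
    ratio_ref = float(ref["q_pdo"]) / sum_ref
    out = []
    for _, row in rows.iterrows():
        s = float(row["q_pdo"] + row["q_glycerol"])
        ratio = float(row["q_pdo"]) / s if s else 0.0
        out.append(SummaryRow(
            label=str(row["strain"]),
            mu=float(row["mu"]),
            q_pdo=float(row["q_pdo"]),
            q_glycerol=float(row["q_glycerol"]),
            sum_products=s,
            fold_vs_ref=s / sum_ref,
            pdo_ratio=ratio,
            ratio_fold_vs_ref=(ratio / ratio_ref) if ratio_ref else float("nan"),
        ))
    return out


def summary_frame(rows: list) -> pd.DataFrame:
    """Display-rounded DataFrame of SummaryRows (TSV-ready)."""
    return pd.DataFrame([r.display() for r in rows])


@dataclass(frozen=True)
class FluxDelta:
    reaction_id: str
    reference: float
    knockout: float

    @property
    def delta(self) -> float:
        return self.knockout - self.reference


def flux_difference_table(reference: FluxState, knockout: FluxState,
                          reaction_subset: Optional[Iterable[str]] = None) -> list:
    """Per-reaction flux shifts, sorted by |delta| descending.

    With ``reaction_subset`` None, all reactions common to both states are
    tabulated; otherwise each listed reaction must be present in both.
    """
    if reaction_subset is None:
        subset = sorted(set(reference.flux) & set(knockout.flux))
    else:
        subset = list(reaction_subset)
        missing = [r for r in subset
                   if r not in reference.flux or r not in knockout.flux]
        if missing:
            raise KeyError(f"reactions missing from a flux state: {missing}")
    rows = [FluxDelta(rid, reference.flux[rid], knockout.flux[rid])
            for rid in subset]
    rows.sort(key=lambda d: (-abs(d.delta), d.reaction_id))
    return rows
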