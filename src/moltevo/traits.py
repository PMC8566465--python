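"""Species trait table: molt-strategy schema, latitude index, coding, summaries.

Schema (CSV, UTF-8): ``species,order,family,molt_strategy,body_mass_g,
mid_latitude_deg,bdpr_flag``.  Strategy strings are case-insensitive members
of {absent, partial, complete}; body mass is in grams (> 0); mid-distribution
latitude is the absolute latitude of the annual-range midpoint in degrees
(0-90); ``bdpr_flag`` marks species placed in the tree without genetic data
(birth-death polytomy resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .mk import STATE_ORDER
from .treeio import Phylogeny

__all__ = [
    "STRATEGIES",
    "STATE_INDEX",
    "TraitTable",
    "load_species_table",
    "latitude_index",
    "code_binary",
    "summarize_by_strategy",
    "order_subsets",
    "match_tree",
]

STRATEGIES: Tuple[str, ...] = STATE_ORDER  # absent < partial < complete
STATE_INDEX: Dict[str, int] = {s: i for i, s in enumerate(STRATEGIES)}

REQUIRED_COLUMNS = ["species", "order", "family", "molt_strategy",
                    "body_mass_g", "mid_latitude_deg", "bdpr_flag"]

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


@dataclass
class TraitTable:
    """A validated species table plus provenance metadata."""

    data: pd.DataFrame = field(repr=False)
    source: Optional[str] = None

    def __post_init__(self):
        self.data = _validate(self.data)

    @property
    def n_species(self) -> int:
        return len(self.data)

    @property
    def species(self) -> List[str]:
        return list(self.data["species"])

    def tip_states(self) -> Dict[str, int]:
        """Map species -> state index (absent=0, partial=1, complete=2)."""
        return {r.species: STATE_INDEX[r.molt_strategy]
                for r in self.data.itertuples(index=False)}

    def family_map(self) -> Dict[str, str]:
        return dict(zip(self.data["species"], self.data["family"]))

    def exclude_bdpr(self) -> "TraitTable":
        return TraitTable(self.data.loc[~self.data["bdpr_flag"]].reset_index(drop=True),
                          source=self.source)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["bdpr_flag"] = out["bdpr_flag"].map({True: "true", False: "false"})
        out.to_csv(path, index=False, lineterminator="\n")


def _coerce_bool(value, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"row {row}: bdpr_flag {value!r} is not a boolean")


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    df = df[REQUIRED_COLUMNS].copy().reset_index(drop=True)
    errors: List[str] = []
    df["species"] = df["species"].astype(str).str.strip()
    dup = df["species"][df["species"].duplicated()]
    for i, name in dup.items():
        errors.append(f"row {i + 2}: duplicate species {name!r}")
    strategies = df["molt_strategy"].astype(str).str.strip().str.lower()
    bad = ~strategies.isin(STRATEGIES)
    for i in np.flatnonzero(bad.to_numpy()):
        errors.append(f"row {i + 2}: molt_strategy {df['molt_strategy'].iat[i]!r} "
                      f"not one of {STRATEGIES}")
    df["molt_strategy"] = strategies
    mass = pd.to_numeric(df["body_mass_g"], errors="coerce")
    for i in np.flatnonzero((~np.isfinite(mass) | (mass <= 0)).to_numpy()):
        errors.append(f"row {i + 2}: body_mass_g {df['body_mass_g'].iat[i]!r} "
                      "must be a finite positive number (grams)")
    df["body_mass_g"] = mass
    lat = pd.to_numeric(df["mid_latitude_deg"], errors="coerce")
    for i in np.flatnonzero((~np.isfinite(lat) | (lat < 0) | (lat > 90)).to_numpy()):
        errors.append(f"row {i + 2}: mid_latitude_deg {df['mid_latitude_deg'].iat[i]!r} "
                      "must lie in [0, 90] degrees")
    df["mid_latitude_deg"] = lat
    flags = []
    for i, v in enumerate(df["bdpr_flag"]):
        try:
            flags.append(_coerce_bool(v, i + 2))
        except ValueError as e:
            errors.append(str(e))
            flags.append(False)
    df["bdpr_flag"] = flags
    if errors:
        raise ValueError("invalid species table:\n" + "\n".join(errors))
    return df


def load_species_table(path) -> TraitTable:
    """Read and validate a species trait CSV; rows failing the schema are
    rejected with row-numbered messages."""
    df = pd.read_csv(path)
    return TraitTable(df, source=str(path))


def latitude_index(lat_south: float, lat_north: float) -> float:
    """Absolute mid-latitude of the full annual range: |(south + north) / 2|.

    Inputs are the signed southern and northern extremes (degrees) of the
    range used over the whole yearly cycle (breeding, migration, wintering);
    a lower index means a longer season available for molt.
    """
    if not (-90.0 <= lat_south <= lat_north <= 90.0):
        raise ValueError(
            f"need -90 <= lat_south <= lat_north <= 90, got ({lat_south}, {lat_north})")
    return abs((lat_south + lat_north) / 2.0)


def code_binary(table: TraitTable) -> Tuple[pd.Series, pd.DataFrame, List[str]]:
    """Binary coding for the regression: complete=1, absent=0, partial dropped.

    Returns ``(y, X, species)`` with X columns (body_mass_g, mid_latitude_deg),
    all indexed by species name.
    """
    df = table.data
    keep = df["molt_strategy"] != "partial"
    sub = df.loc[keep]
    if sub.empty or sub["molt_strategy"].nunique() < 2:
        raise ValueError("binary coding needs both complete and absent species")
    y = (sub["molt_strategy"] == "complete").astype(int)
    y.index = sub["species"]
    y.name = "complete_molt"
    X = sub[["body_mass_g", "mid_latitude_deg"]].copy()
    X.index = sub["species"]
    return y, X, list(sub["species"])


def summarize_by_strategy(table: TraitTable) -> pd.DataFrame:
    """Group statistics (n, mean, sample SD, min, max) for mass and latitude,
    comparing complete-molt species against partial+absent species."""
    df = table.data
    groups = {
        "complete": df["molt_strategy"] == "complete",
        "partial_absent": df["molt_strategy"] != "complete",
    }
    rows = []
    for gname, mask in groups.items():
        sub = df.loc[mask]
        for var in ("body_mass_g", "mid_latitude_deg"):
            vals = sub[var]
            if len(vals) == 0:
                rows.append({"group": gname, "variable": var, "n": 0,
                             "mean": float("nan"), "sd": float("nan"),
                             "min": float("nan"), "max": float("nan"),
                             "empty": True})
                continue
            rows.append({"group": gname, "variable": var, "n": int(len(vals)),
                         "mean": float(vals.mean()),
                         "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                         "min": float(vals.min()), "max": float(vals.max()),
                         "empty": False})
    return pd.DataFrame(rows)


def order_subsets(table: TraitTable, min_per_category: int = 21) -> List[str]:
    """Orders with at least ``min_per_category`` (default > 20, i.e. 21)
    species in *each* of the complete and absent categories."""
    df = table.data
    counts = (df[df["molt_strategy"].isin(["complete", "absent"])]
              .groupby(["order", "molt_strategy"]).size().unstack(fill_value=0))
    eligible = []
    for order, row in counts.iterrows():
        if row.get("complete", 0) >= min_per_category and \
           row.get("absent", 0) >= min_per_category:
            eligible.append(order)
    return sorted(eligible)


def _normalize_name(name: str) -> str:
    return name.strip().casefold().replace(" ", "_")


def match_tree(table: TraitTable, tree: Phylogeny) -> Dict[str, str]:
    """Match species names to tip labels (exact after underscore/space
    normalization and case folding).  Returns species -> tip label; raises
    with the full lists of unmatched names on either side."""
    tip_norm = {}
    for lbl in tree.tip_labels:
        tip_norm.setdefault(_normalize_name(lbl), lbl)
    mapping = {}
    unmatched = []
    for sp in table.species:
        lbl = tip_norm.get(_normalize_name(sp))
        if lbl is None:
            unmatched.append(sp)
        else:
            mapping[sp] = lbl
    matched_tips = set(mapping.values())
    extra_tips = [t for t in tree.tip_labels if t not in matched_tips]
    if unmatched:
        raise KeyError(
            f"{len(unmatched)} species not found in the tree: {unmatched[:10]}"
            + ("..." if len(unmatched) > 10 else "")
            + (f"; tree tips without table rows: {extra_tips[:10]}" if extra_tips else ""))
    return mapping
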