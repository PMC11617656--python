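"""Domain types, units, validation and CSV I/O shared by all pipeline stages.

The experimental unit is a single *Pinus edulis* tree carrying a watering
group (watered vs drought), a drought stratum, girdle/inoculation flags,
predawn shoot water potential, inner-bark osmometry, and pre-/post-inoculation
mono+sesquiterpene (MST) and nonstructural-carbohydrate (NSC) measurements.

Units are fixed package-wide: water potentials in MPa (<= 0), terpene
concentrations in mg per g dry weight, NSC component pools in % dry weight,
osmolality in mmol kg^-1, temperature in K. The one sanctioned unit
conversion, % DW <-> mg g^-1, lives in :func:`pct_dw_to_mg_per_g` /
:func:`mg_per_g_to_pct_dw` and nowhere else.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA_VERSION",
    "NSC_COMPONENTS",
    "SchemaError",
    "ValidationError",
    "NSCProfile",
    "TerpeneProfile",
    "TreeRecord",
    "Cohort",
    "pct_dw_to_mg_per_g",
    "mg_per_g_to_pct_dw",
    "total_mst",
    "read_cohort",
    "write_cohort",
    "write_results",
]

SCHEMA_VERSION = "1"

NSC_COMPONENTS = ("starch", "sucrose", "glucose", "fructose")

WATER_GROUPS = ("watered", "drought")
DROUGHT_STRATA = ("well_watered", "mild", "moderate")

#: Required columns of the tree-level cohort CSV, in canonical order.
COHORT_COLUMNS = (
    "tree_id",
    "water_group",
    "drought_stratum",
    "girdled",
    "inoculated",
    "psi_pd",
    "osmolality",
    "chamber_temp",
    "mst_pre",
    "mst_post",
    "starch_pre",
    "sucrose_pre",
    "glucose_pre",
    "fructose_pre",
    "starch_post",
    "sucrose_post",
    "glucose_post",
    "fructose_post",
)


class SchemaError(ValueError):
    """The input file does not match the documented cohort schema."""


class ValidationError(ValueError):
    """A field value violates a domain invariant (names the offending tree)."""


def pct_dw_to_mg_per_g(x: float) -> float:
    """Convert % dry weight to mg per g dry weight (1 % DW = 10 mg g^-1)."""
    return 10.0 * x


def mg_per_g_to_pct_dw(x: float) -> float:
    """Inverse of :func:`pct_dw_to_mg_per_g`."""
    return x / 10.0


@dataclass(frozen=True)
class NSCProfile:
    """Nonstructural-carbohydrate pools of one tissue sample, % dry weight."""

    starch: float
    sucrose: float
    glucose: float
    fructose: float

    def __post_init__(self) -> None:
        for name in NSC_COMPONENTS:
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"NSC component {name}={v!r} outside [0, 100] % DW"
                )

    @property
    def total_nsc(self) -> float:
        """Total NSC: starch + sucrose + glucose + fructose (% DW)."""
        return self.starch + self.sucrose + self.glucose + self.fructose

    @property
    def total_sugar(self) -> float:
        """Soluble sugars: total NSC minus starch (% DW)."""
        return self.total_nsc - self.starch

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in NSC_COMPONENTS}


@dataclass(frozen=True)
class TerpeneProfile:
    """Per-compound terpene concentration vector at one timepoint.

    Concentrations are mg per g dry weight.  ``relative()`` returns the
    compositional (unit-sum) view used for Bray-Curtis dissimilarity.
    """

    compound_names: tuple[str, ...]
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "compound_names", tuple(self.compound_names))
        if conc.ndim != 1 or conc.size != len(self.compound_names):
            raise ValidationError(
                "concentration vector length does not match compound names"
            )
        if np.any(conc < 0):
            raise ValidationError("negative terpene concentration")

    @property
    def total(self) -> float:
        return float(self.concentrations.sum())

    def relative(self) -> np.ndarray:
        """Relative composition (sums to 1); requires a positive total."""
        tot = self.total
        if tot <= 0:
            raise ValidationError("relative composition undefined for zero total")
        return self.concentrations / tot


def total_mst(profile: TerpeneProfile) -> float:
    """Total mono+sesquiterpene concentration of a profile (mg g^-1 DW)."""
    return profile.total


@dataclass(frozen=True)
class TreeRecord:
    """One experimental unit (a single tree)."""

    tree_id: str
    water_group: str
    drought_stratum: str
    girdled: bool
    inoculated: bool
    psi_pd: float
    mst_pre: float
    mst_post: float | None
    nsc_pre: NSCProfile
    nsc_post: NSCProfile | None = None
    osmolality: float | None = None
    chamber_temp: float | None = None

    def __post_init__(self) -> None:
        tid = self.tree_id
        if self.water_group not in WATER_GROUPS:
            raise ValidationError(f"{tid}: unknown water_group {self.water_group!r}")
        if self.drought_stratum not in DROUGHT_STRATA:
            raise ValidationError(
                f"{tid}: unknown drought_stratum {self.drought_stratum!r}"
            )
        if (self.drought_stratum == "well_watered") != (self.water_group == "watered"):
            raise ValidationError(
                f"{tid}: stratum {self.drought_stratum!r} inconsistent with "
                f"water_group {self.water_group!r}"
            )
        if self.psi_pd > 0:
            raise ValidationError(f"{tid}: psi_pd={self.psi_pd} must be <= 0 MPa")
        if self.mst_pre < 0:
            raise ValidationError(f"{tid}: mst_pre={self.mst_pre} must be >= 0")
        if self.mst_post is not None and self.mst_post < 0:
            raise ValidationError(f"{tid}: mst_post={self.mst_post} must be >= 0")
        if self.osmolality is not None and self.osmolality < 0:
            raise ValidationError(f"{tid}: osmolality must be >= 0")
        if self.chamber_temp is not None and self.chamber_temp <= 0:
            raise ValidationError(f"{tid}: chamber_temp must be > 0 K")

    @property
    def treatment(self) -> str:
        """Treatment-cell label: C, G, I or I+G."""
        if self.inoculated:
            return "I+G" if self.girdled else "I"
        return "G" if self.girdled else "C"

    @property
    def has_post(self) -> bool:
        """False for trees whose post-inoculation tissue could not be sampled."""
        return self.mst_post is not None


@dataclass
class Cohort:
    """A set of trees plus optional per-compound terpene matrices.

    ``terpenes_pre`` / ``terpenes_post`` are wide DataFrames indexed by
    tree_id with one column per compound (mg g^-1 DW).  ``provenance``
    records the generator parameters and seed or the file paths read.
    """

    trees: list[TreeRecord]
    terpenes_pre: pd.DataFrame | None = None
    terpenes_post: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.tree_id for t in self.trees]
        if len(set(ids)) != len(ids):
            raise ValidationError("tree_ids are not unique")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[TreeRecord]:
        return iter(self.trees)

    def subset(self, predicate) -> "Cohort":
        """New cohort containing the trees for which ``predicate`` is true."""
        trees = [t for t in self.trees if predicate(t)]
        ids = [t.tree_id for t in trees]
        tp = self.terpenes_pre.loc[ids] if self.terpenes_pre is not None else None
        to = (
            self.terpenes_post.loc[[i for i in ids if i in self.terpenes_post.index]]
            if self.terpenes_post is not None
            else None
        )
        return Cohort(trees, tp, to, dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        """Tree-level table in the canonical CSV column order."""
        rows = []
        for t in self.trees:
            row = {
                "tree_id": t.tree_id,
                "water_group": t.water_group,
                "drought_stratum": t.drought_stratum,
                "girdled": t.girdled,
                "inoculated": t.inoculated,
                "psi_pd": t.psi_pd,
                "osmolality": np.nan if t.osmolality is None else t.osmolality,
                "chamber_temp": np.nan if t.chamber_temp is None else t.chamber_temp,
                "mst_pre": t.mst_pre,
                "mst_post": np.nan if t.mst_post is None else t.mst_post,
            }
            for name in NSC_COMPONENTS:
                row[f"{name}_pre"] = getattr(t.nsc_pre, name)
            for name in NSC_COMPONENTS:
                row[f"{name}_post"] = (
                    np.nan if t.nsc_post is None else getattr(t.nsc_post, name)
                )
            rows.append(row)
        return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def _tree_from_row(row: Mapping) -> TreeRecord:
    def opt(v):
        return None if pd.isna(v) else float(v)

    nsc_pre = NSCProfile(
        **{name: float(row[f"{name}_pre"]) for name in NSC_COMPONENTS}
    )
    post_vals = {name: row[f"{name}_post"] for name in NSC_COMPONENTS}
    nsc_post = (
        None
        if all(pd.isna(v) for v in post_vals.values())
        else NSCProfile(**{k: float(v) for k, v in post_vals.items()})
    )
    return TreeRecord(
        tree_id=str(row["tree_id"]),
        water_group=str(row["water_group"]),
        drought_stratum=str(row["drought_stratum"]),
        girdled=_parse_bool(row["girdled"]),
        inoculated=_parse_bool(row["inoculated"]),
        psi_pd=float(row["psi_pd"]),
        osmolality=opt(row["osmolality"]),
        chamber_temp=opt(row["chamber_temp"]),
        mst_pre=float(row["mst_pre"]),
        mst_post=opt(row["mst_post"]),
        nsc_pre=nsc_pre,
        nsc_post=nsc_post,
    )


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise SchemaError(f"cannot parse boolean value {v!r}")


def read_cohort(
    path: str | Path,
    schema_version: str = SCHEMA_VERSION,
    terpenes_pre: str | Path | None = None,
    terpenes_post: str | Path | None = None,
) -> Cohort:
    """Read and validate a tree-level cohort CSV (plus optional terpene matrices).

    Rows with a missing ``mst_post`` are retained and flagged via
    ``TreeRecord.has_post`` — they correspond to trees whose desiccated inner
    bark could not be sampled after inoculation and must not be dropped
    silently.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} missing required column(s): {missing}")
    trees = [_tree_from_row(row) for _, row in df.iterrows()]
    cohort = Cohort(trees, provenance={"path": str(path)})
    if terpenes_pre is not None:
        cohort.terpenes_pre = _read_terpene_matrix(terpenes_pre)
    if terpenes_post is not None:
        cohort.terpenes_post = _read_terpene_matrix(terpenes_post)
    return cohort


def _read_terpene_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "tree_id" not in df.columns:
        raise SchemaError(f"terpene matrix {path} missing tree_id column")
    df = df.set_index("tree_id")
    df.index = df.index.astype(str)
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValidationError(f"negative terpene concentration in {path}")
    return df.astype(float)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, str]:
    """Write cohort.csv (and terpene matrices if present); returns path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"cohort": str(out / "cohort.csv")}
    cohort.to_frame().to_csv(paths["cohort"], index=False, float_format="%.10g")
    for key, df in (("terpenes_pre", cohort.terpenes_pre),
                    ("terpenes_post", cohort.terpenes_post)):
        if df is not None:
            p = out / f"{key}.csv"
            df.to_csv(p, index=True, float_format="%.10g")
            paths[key] = str(p)
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    results: Mapping[str, pd.DataFrame],
    model_summaries: Mapping | None,
    out_dir: str | Path,
) -> dict:
    """Write result tables as CSV plus a JSON report and a checksum manifest.

    ``results`` maps table name (e.g. ``induction``) to a DataFrame; each is
    written as ``<name>.csv``.  ``model_summaries`` (JSON-serialisable) is
    written as ``models.json``.  Re-running with identical inputs yields
    byte-identical files, hence identical checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in results.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    if model_summaries is not None:
        p = out / "models.json"
        p.write_text(json.dumps(model_summaries, indent=2, sort_keys=True,
                                default=_json_default) + "\n")
        written.append(p)
    manifest = {
        "files": [
            {"name": p.name, "sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in sorted(written)
        ]
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
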