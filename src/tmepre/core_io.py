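"""Data model and file I/O.

Expression matrices are genes x samples, log2 scale, exchanged as TSV with a
header row of sample ids and gene ids in the first column.  Sample annotations
are TSV with ``sample_id`` and ``msi_status`` required and optional survival /
response / cohort columns.  Fitted models serialize to JSON with an explicit
schema version.

Gene identifiers are symbols throughout; probe-to-symbol mapping is the
caller's responsibility.  Missing expression values are rejected, never
imputed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MSI_TOKENS = ("MSI", "MSI-L", "MSS", "Unknown")
RESPONSE_TOKENS = ("responder", "nonresponder", "unknown")

#: Genes of the exhaustion-state signature that are primarily expressed by
#: CD8+ T cells (seven hematopoiesis-restricted genes plus the two inhibitory
#: receptors PDCD1/HAVCR2 used to define early terminal exhaustion).
DEFAULT_CD8_RESTRICTED_GENES = (
    "CCL5", "CD2", "CD48", "CD84", "FAM78A", "HCST", "IL21R",
    "HAVCR2", "PDCD1",
)

MODEL_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised for malformed input files (message names the offending line)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression values.

    Invariants enforced on construction: unique gene and sample identifiers,
    dimensions matching the identifier lists, all values finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dupes):
                raise ValueError(f"duplicate {name} id(s): {sorted(set(dupes))}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value for gene {self.gene_ids[bad[0]]!r},"
                f" sample {self.sample_ids[bad[1]]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def gene_values(self, gene: str) -> np.ndarray:
        """Expression of one gene across all samples (1-D view)."""
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in matrix") from None

    def subset_genes(self, genes: list[str]) -> np.ndarray:
        """Rows for ``genes`` in the given order; raises listing missing genes."""
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise KeyError(f"genes missing from matrix: {missing}")
        idx = [self._gene_index[g] for g in genes]
        return self.values[idx]

    def sample_indices(self, sample_ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples missing from matrix: {missing}")
        return np.asarray([pos[s] for s in sample_ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


def read_expression_matrix(path) -> ExpressionMatrix:
    """Parse a genes-x-samples TSV; errors name the offending line."""
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty or missing header line")
        sample_ids = header.rstrip("\n").split("\t")[1:]
        n = len(sample_ids)
        gene_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n + 1:
                raise FormatError(
                    f"{path}, line {lineno}: expected {n + 1} columns, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            try:
                rows.append(np.asarray(fields[1:], dtype=float))
            except ValueError:
                for col, cell in enumerate(fields[1:]):
                    try:
                        float(cell)
                    except ValueError:
                        raise FormatError(
                            f"{path}, line {lineno}: non-numeric value {cell!r} "
                            f"for gene {fields[0]!r}, sample {sample_ids[col]!r}"
                        ) from None
                raise
    seen: set[str] = set()
    for g in gene_ids:
        if g in seen:
            raise FormatError(f"{path}: duplicate gene id {g!r}")
        seen.add(g)
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample id(s) {dupes}")
    values = np.vstack(rows) if rows else np.empty((0, n))
    if not np.isfinite(values).all():
        raise FormatError(f"{path}: matrix contains non-finite values")
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


ANNOTATION_COLUMNS = ("sample_id", "msi_status", "surv_time", "surv_event",
                      "response", "cohort")


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an annotation table (see module docstring)."""
    if "sample_id" not in ann.columns or "msi_status" not in ann.columns:
        raise FormatError("annotations require columns sample_id and msi_status")
    ann = ann.copy()
    ann["sample_id"] = ann["sample_id"].astype(str)
    if ann["sample_id"].duplicated().any():
        dupes = sorted(ann.loc[ann["sample_id"].duplicated(), "sample_id"].unique())
        raise FormatError(f"duplicate sample_id(s) in annotations: {dupes}")
    bad = ~ann["msi_status"].isin(MSI_TOKENS)
    if bad.any():
        tok = sorted(ann.loc[bad, "msi_status"].astype(str).unique())
        raise FormatError(
            f"unknown msi_status token(s) {tok}; accepted tokens: {list(MSI_TOKENS)}"
        )
    if "response" in ann.columns:
        ann["response"] = ann["response"].fillna("unknown")
        bad = ~ann["response"].isin(RESPONSE_TOKENS)
        if bad.any():
            tok = sorted(ann.loc[bad, "response"].astype(str).unique())
            raise FormatError(
                f"unknown response token(s) {tok}; accepted: {list(RESPONSE_TOKENS)}"
            )
    else:
        ann["response"] = "unknown"
    if "cohort" not in ann.columns:
        ann["cohort"] = ""
    has_time = "surv_time" in ann.columns
    has_event = "surv_event" in ann.columns
    if has_time != has_event:
        raise FormatError("surv_time and surv_event must be provided together")
    if has_time:
        ann["surv_time"] = pd.to_numeric(ann["surv_time"], errors="raise")
        ev = ann["surv_event"]
        if ev.dtype == object:
            ev = ev.map({"True": True, "False": False, "1": True, "0": False,
                         True: True, False: False, 1: True, 0: False, "": pd.NA})
        ann["surv_event"] = pd.array(ev, dtype="boolean")
        mismatch = ann["surv_time"].isna() != ann["surv_event"].isna()
        if mismatch.any():
            sid = ann.loc[mismatch, "sample_id"].iloc[0]
            raise FormatError(
                f"sample {sid!r}: surv_time and surv_event must be absent or present together"
            )
        if (ann["surv_time"].dropna() < 0).any():
            raise FormatError("negative surv_time")
    else:
        ann["surv_time"] = pd.array([pd.NA] * len(ann), dtype="Float64")
        ann["surv_event"] = pd.array([pd.NA] * len(ann), dtype="boolean")
    return ann[list(ANNOTATION_COLUMNS)]


def read_annotations(path) -> pd.DataFrame:
    try:
        ann = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise FormatError(f"{path}: {exc}") from exc
    try:
        return validate_annotations(ann)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_annotations(ann: pd.DataFrame, path) -> None:
    validate_annotations(ann).to_csv(path, sep="\t", index=False)


@dataclass
class CentroidSignature:
    """A fitted nearest-centroid signature.

    score(sample) = (||z - centroid_neg|| - ||z - centroid_pos||) / n_genes
    on per-gene standardized values z = (x - mu) / sigma, so higher scores mean
    closer to the positive class.  ``cutoff`` is None until optimized.
    """

    genes: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    centroid_pos: np.ndarray
    centroid_neg: np.ndarray
    cutoff: float | None = None
    positive_label: str = "POS"

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if not self.genes:
            raise ValueError("signature gene list must be nonempty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")
        for name in ("mu", "sigma", "centroid_pos", "centroid_neg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.genes),):
                raise ValueError(f"{name} length does not match gene list")
            setattr(self, name, arr)
        if (self.sigma <= 0).any():
            bad = [g for g, s in zip(self.genes, self.sigma) if s <= 0]
            raise ValueError(f"non-positive sigma for gene(s) {bad}")
        if self.cutoff is not None:
            self.cutoff = float(self.cutoff)

    def restrict(self, genes: list[str]) -> "CentroidSignature":
        """Signature restricted to ``genes`` (must be a nonempty subset)."""
        keep = [g for g in self.genes if g in set(genes)]
        if not keep:
            raise ValueError("restriction has empty intersection with signature genes")
        idx = [self.genes.index(g) for g in keep]
        return CentroidSignature(
            keep, self.mu[idx], self.sigma[idx],
            self.centroid_pos[idx], self.centroid_neg[idx],
            cutoff=None, positive_label=self.positive_label,
        )

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "centroid_pos": self.centroid_pos.tolist(),
            "centroid_neg": self.centroid_neg.tolist(),
            "cutoff": self.cutoff,
            "positive_label": self.positive_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CentroidSignature":
        return cls(
            d["genes"], np.asarray(d["mu"]), np.asarray(d["sigma"]),
            np.asarray(d["centroid_pos"]), np.asarray(d["centroid_neg"]),
            cutoff=d.get("cutoff"), positive_label=d.get("positive_label", "POS"),
        )


@dataclass
class TmepreModel:
    """The full two-component model.

    ``tme1`` scores CD8+ T-cell infiltration; ``tme2`` scores whether
    infiltrating CD8+ T cells are still responsive (higher = not terminally
    exhausted).  Decision-rule parameters: the infiltration marker percentile
    used during training and the within-cohort quantiles used by the
    validation rule on platforms where trained cutoffs do not transfer.
    """

    tme1: CentroidSignature
    tme2: CentroidSignature
    marker_cd8a: str = "CD8A"
    marker_pd1: str = "PDCD1"
    marker_tim3: str = "HAVCR2"
    infiltration_percentile: float = 0.40
    validation_low_quantile: float = 0.25
    validation_high_quantile: float = 0.75
    cd8_restricted_genes: list[str] = field(
        default_factory=lambda: list(DEFAULT_CD8_RESTRICTED_GENES))

    def __post_init__(self) -> None:
        if not (0 < self.validation_low_quantile < self.validation_high_quantile < 1):
            raise ValueError(
                "require 0 < validation_low_quantile < validation_high_quantile < 1"
            )
        if not 0 < self.infiltration_percentile < 1:
            raise ValueError("infiltration_percentile must be in (0, 1)")
        if self.marker_cd8a in self.tme1.genes:
            raise ValueError(
                f"infiltration marker {self.marker_cd8a!r} must not appear in the "
                "infiltration signature"
            )

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "tme1": self.tme1.to_dict(),
            "tme2": self.tme2.to_dict(),
            "marker_cd8a": self.marker_cd8a,
            "marker_pd1": self.marker_pd1,
            "marker_tim3": self.marker_tim3,
            "infiltration_percentile": self.infiltration_percentile,
            "validation_low_quantile": self.validation_low_quantile,
            "validation_high_quantile": self.validation_high_quantile,
            "cd8_restricted_genes": list(self.cd8_restricted_genes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TmepreModel":
        version = d.get("schema_version")
        if version != MODEL_SCHEMA_VERSION:
            raise FormatError(
                f"unsupported model schema version {version!r}; "
                f"expected {MODEL_SCHEMA_VERSION}"
            )
        return cls(
            tme1=CentroidSignature.from_dict(d["tme1"]),
            tme2=CentroidSignature.from_dict(d["tme2"]),
            marker_cd8a=d["marker_cd8a"],
            marker_pd1=d["marker_pd1"],
            marker_tim3=d["marker_tim3"],
            infiltration_percentile=d["infiltration_percentile"],
            validation_low_quantile=d["validation_low_quantile"],
            validation_high_quantile=d["validation_high_quantile"],
            cd8_restricted_genes=list(d["cd8_restricted_genes"]),
        )


def save_model(model: TmepreModel, path) -> None:
    d = model.to_dict()
    for comp in ("tme1", "tme2"):
        for v in d[comp]["mu"] + d[comp]["sigma"]:
            if not math.isfinite(v):
                raise ValueError("refusing to save model with non-finite parameters")
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(d, fh, indent=1)
        fh.write("\n")


def load_model(path) -> TmepreModel:
    with open(path, "rt", encoding="utf-8") as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not a valid model file ({exc})") from None
    return TmepreModel.from_dict(d)
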