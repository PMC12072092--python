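"""Genotype tables, run configuration and attributable output files.

The canonical genotype exchange format is a TSV with header

    sample_id  sex  group  rs11178998  rs4290270  rs7305115  HTTLPR  uVNTR

where autosomal genotype cells are "X/Y" (allele order irrelevant) and the
male uVNTR cell is a single allele.  Every file this package writes starts
with ``#`` comment lines carrying the package version, the seed and a hash
of the effective configuration, so reruns are attributable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .genotype import GenotypeError, GenotypeRecord, VariantDef, default_variant_defs
from .kinetics import ModelParameters

__all__ = [
    "GENOTYPE_COLUMNS",
    "RunConfig",
    "read_genotype_table",
    "write_genotype_table",
    "read_config",
    "provenance_header",
    "write_table",
]

#: column name in the TSV -> locus id in the variant definitions
COLUMN_TO_LOCUS = {
    "rs11178998": "rs11178998",
    "rs4290270": "rs4290270",
    "rs7305115": "rs7305115",
    "HTTLPR": "5-HTTLPR",
    "uVNTR": "uVNTR",
}
GENOTYPE_COLUMNS = ["sample_id", "sex", "group", *COLUMN_TO_LOCUS]


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration; unknown keys are rejected by name."""

    params: ModelParameters = field(default_factory=ModelParameters)
    scale: Mapping[str, float] | None = None
    t_end: float = 3.0
    dt: float = 0.01
    n: int = 140
    female_fraction: float = 0.657
    allele_freqs: Mapping[str, Mapping[str, float]] | None = None
    seed: int = 0
    group_label: str = "unaffected"

    def digest(self) -> str:
        blob = json.dumps(
            {
                "params": self.params.to_dict(),
                "scale": dict(self.scale) if self.scale else None,
                "t_end": self.t_end,
                "dt": self.dt,
                "n": self.n,
                "female_fraction": self.female_fraction,
                "allele_freqs": {k: dict(v) for k, v in self.allele_freqs.items()}
                if self.allele_freqs
                else None,
                "seed": self.seed,
                "group_label": self.group_label,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def read_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON config; model-parameter keys sit under ``params``."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown config key(s): {sorted(unknown)}")
    if "params" in raw:
        raw["params"] = ModelParameters.from_dict(raw["params"])
    return RunConfig(**raw)


def _reference_alleles(vd: VariantDef, sex: str) -> tuple[str, ...]:
    ref = next(a for a, e in vd.normalized_effect.items() if abs(e - 1.0) < 1e-12)
    n = 1 if (vd.chromosome_mode == "X-linked" and sex == "male") else 2
    return (ref,) * n


def _parse_cell(
    cell: str, column: str, row: int, sex: str, vd: VariantDef, fill_missing: bool
) -> tuple[str, ...]:
    cell = str(cell).strip()
    if not cell or cell.lower() == "nan":
        if fill_missing:
            filled = _reference_alleles(vd, sex)
            logging.getLogger("serosim").warning(
                "row %d: missing genotype at %s filled with reference %s",
                row, column, "/".join(filled),
            )
            return filled
        raise GenotypeError(f"row {row}: missing genotype in column {column!r}")
    parts = tuple(p.strip() for p in cell.split("/")) if "/" in cell else (cell,)
    return parts


def read_genotype_table(
    path: str | Path,
    defs: Mapping[str, VariantDef] | None = None,
    fill_missing_with_reference: bool = False,
) -> list[GenotypeRecord]:
    """Read and validate the genotype TSV into records.

    Raises :class:`~serosim.genotype.GenotypeError` naming the offending
    row and column on any unknown allele, wrong allele count (e.g. two
    uVNTR alleles for a male) or missing column.  Empty genotype cells are
    a hard error unless ``fill_missing_with_reference`` is set, in which
    case they are filled with the reference genotype and a warning logged.
    """
    defs = defs if defs is not None else default_variant_defs()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise GenotypeError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        sex = str(row["sex"]).strip().lower()
        genotype = {
            locus: _parse_cell(
                row[col], col, i + 1, sex, defs[locus], fill_missing_with_reference
            )
            for col, locus in COLUMN_TO_LOCUS.items()
        }
        try:
            rec = GenotypeRecord(
                sample_id=str(row["sample_id"]),
                sex=str(row["sex"]).strip().lower(),
                group=str(row["group"]),
                genotype=genotype,
            )
            rec.validate(defs)
        except GenotypeError as exc:
            raise GenotypeError(f"{path} row {i + 1}: {exc}") from None
        records.append(rec)
    return records


def provenance_header(seed: int | None = None, config_digest: str | None = None) -> str:
    parts = [f"# serosim v{__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if config_digest is not None:
        parts.append(f"# config: {config_digest}")
    return "\n".join(parts) + "\n"


def write_genotype_table(
    records: Sequence[GenotypeRecord],
    path: str | Path,
    seed: int | None = None,
    config_digest: str | None = None,
) -> None:
    """Write records as the canonical TSV (with provenance comments)."""
    rows = []
    for rec in records:
        row = {"sample_id": rec.sample_id, "sex": rec.sex, "group": rec.group}
        for col, locus in COLUMN_TO_LOCUS.items():
            row[col] = "/".join(rec.genotype[locus])
        rows.append(row)
    df = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config_digest))
        df.to_csv(fh, sep="\t", index=False)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_digest: str | None = None,
) -> None:
    """Write any result table as CSV with the provenance comment header."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config_digest))
        df.to_csv(fh, index=False)
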