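"""Packaged study tables: 141 training compounds and 7 external alcohols.

The training table carries, per compound, the I_SET descriptor, calculated
log P values from five methods (I_SET, Ghose/Crippen, AlogP, ClogP, MlogP)
and — where determined — the experimental octanol/water log P.  The
external table holds seven alcohols kept out of every calibration.  A
printed per-class statistics table is packaged alongside so recomputed
regressions can be compared cell by cell.

Numbers are stored exactly as published apart from mechanical
normalisation (decimal commas to points, ASCII minus signs); each touched
cell carries a flag.  Known anomalies are flagged, never edited: the
Isobutyl Acetate descriptor value is internally inconsistent with the
ester calibration (``suspect_typo``), and the published intercept of the
alcohol calibration is printed without a sign — consistency with the
calculated-log P column fixes it as negative
(``intercept_sign_normalized``).
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .calibration import CalibrationModel, RegressionReport, fit_ols, loo_q2

__all__ = [
    "CompoundRecord",
    "ClassSummary",
    "CLASSES",
    "METHODS",
    "DataIntegrityError",
    "load_table1",
    "load_table3",
    "load_table2_printed",
    "class_subset",
    "reproduce_table2",
    "write_table",
    "data_path",
]

CLASSES = ("hydrocarbon", "aldehyde", "ketone", "ester", "alcohol")
METHODS = ("iset", "ghose_crippen", "alogp", "clogp", "mlogp")

_METHOD_COLUMN = {m: f"logp_{m}" for m in METHODS}


class DataIntegrityError(RuntimeError):
    """A packaged data file does not match its recorded checksum."""


@dataclass(frozen=True)
class CompoundRecord:
    """One compound of the study set."""

    name: str
    compound_class: str
    iset: float
    calc_logp: dict[str, float] = field(default_factory=dict)
    exp_logp: float | None = None
    number: str = ""
    flags: tuple[str, ...] = ()
    raw_row: tuple[str, ...] = ()

    @property
    def has_exp(self) -> bool:
        return self.exp_logp is not None


@dataclass(frozen=True)
class ClassSummary:
    """Recomputed calibration statistics for one class/method cell block."""

    compound_class: str
    method: str
    n: int
    model: CalibrationModel
    report: RegressionReport


def data_path(filename: str) -> Path:
    """Path to a packaged data file."""
    return Path(resources.files("iset.data") / filename)


def _verify(path: Path) -> None:
    manifest = Path(resources.files("iset.data") / "_checksums.json")
    if not manifest.exists():
        return
    recorded = json.loads(manifest.read_text()).get(path.name)
    if recorded is None:
        return
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != recorded:
        raise DataIntegrityError(
            f"{path.name}: sha256 {digest} does not match recorded {recorded}"
        )


def _read_rows(path: Path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        rows = [row + [""] * (len(header) - len(row)) for row in reader]
    return header, rows


def _opt_float(cell: str) -> float | None:
    cell = cell.strip()
    return None if cell == "" else float(cell)


def load_table1(path: Path | None = None) -> list[CompoundRecord]:
    """Load the 141-compound training table.

    Missing experimental cells become ``None`` (never zero); flagged rows
    are loaded verbatim with their annotations attached.
    """
    path = path or data_path("table1.tsv")
    _verify(path)
    header, rows = _read_rows(path)
    col = {name: k for k, name in enumerate(header)}
    records = []
    for row in rows:
        calc = {m: float(row[col[_METHOD_COLUMN[m]]]) for m in METHODS}
        flags = tuple(t for t in row[col["flags"]].split(";") if t)
        records.append(
            CompoundRecord(
                name=row[col["name"]],
                compound_class=row[col["class"]],
                iset=float(row[col["iset"]]),
                calc_logp=calc,
                exp_logp=_opt_float(row[col["logp_exp"]]),
                number=row[col["no"]],
                flags=flags,
                raw_row=tuple(row),
            )
        )
    return records


def load_table3(path: Path | None = None) -> list[CompoundRecord]:
    """Load the seven external-validation alcohols.

    Each record carries the experimental log P, the descriptor value and
    the five published per-method deviations (experimental - predicted),
    stored under ``calc_logp`` keys ``delta_<method>``.
    """
    path = path or data_path("table3.tsv")
    _verify(path)
    header, rows = _read_rows(path)
    col = {name: k for k, name in enumerate(header)}
    records = []
    for row in rows:
        deltas = {
            f"delta_{m}": float(row[col[f"delta_{m}"]]) for m in METHODS
        }
        records.append(
            CompoundRecord(
                name=row[col["name"]],
                compound_class="alcohol",
                iset=float(row[col["iset"]]),
                calc_logp=deltas,
                exp_logp=float(row[col["logp_exp"]]),
                number=row[col["no"]],
                flags=tuple(t for t in row[col["flags"]].split(";") if t),
                raw_row=tuple(row),
            )
        )
    return records


def load_table2_printed(path: Path | None = None) -> list[dict]:
    """Published per-class regression statistics, one dict per class/method."""
    path = path or data_path("table2.tsv")
    _verify(path)
    header, rows = _read_rows(path)
    col = {name: k for k, name in enumerate(header)}
    out = []
    for row in rows:
        out.append(
            {
                "class": row[col["class"]],
                "method": row[col["method"]],
                "n": int(row[col["n"]]),
                "a": float(row[col["a"]]),
                "b": float(row[col["b"]]),
                "r2": float(row[col["r2"]]),
                "r": float(row[col["r"]]),
                "f": float(row[col["f"]]),
                "s": float(row[col["s"]]),
                "rcv2": float(row[col["rcv2"]]),
                "flags": tuple(t for t in row[col["flags"]].split(";") if t),
            }
        )
    return out


def class_subset(
    records: Sequence[CompoundRecord],
    compound_class: str,
    require_exp: bool = False,
) -> list[CompoundRecord]:
    """Stable-order subset of one compound class."""
    if compound_class not in CLASSES:
        raise KeyError(
            f"unknown compound class {compound_class!r}; expected one of {CLASSES}"
        )
    subset = [r for r in records if r.compound_class == compound_class]
    if require_exp:
        subset = [r for r in subset if r.has_exp]
    return subset


def reproduce_table2(
    records: Sequence[CompoundRecord] | None = None,
    method: str = "iset",
    x_kind: Literal["calculated_logp", "raw_iset"] = "calculated_logp",
) -> list[ClassSummary]:
    """Refit the per-class calibrations from the packaged training table.

    For each class, experimental log P (Y) is regressed on either the
    method's calculated-log P column or, for ``x_kind="raw_iset"``, the
    raw descriptor (defined for ``method="iset"`` only).  r, r^2, s, F and
    the leave-one-out q^2 are recomputed from scratch; r, r^2, s and q^2
    are invariant under the affine difference between the two predictor
    choices.
    """
    if method not in METHODS:
        raise KeyError(f"unknown method {method!r}; expected one of {METHODS}")
    if x_kind == "raw_iset" and method != "iset":
        raise ValueError("raw_iset predictor is only defined for the iset method")
    if records is None:
        records = load_table1()
    out = []
    for cls in CLASSES:
        subset = class_subset(records, cls, require_exp=True)
        if x_kind == "raw_iset":
            x = [r.iset for r in subset]
        else:
            x = [r.calc_logp[method] for r in subset]
        y = [r.exp_logp for r in subset]
        model, report = fit_ols(x, y, x_kind=x_kind, class_label=cls, with_q2=True)
        out.append(
            ClassSummary(
                compound_class=cls, method=method, n=len(subset),
                model=model, report=report,
            )
        )
    return out


def compare_table2(
    method: str = "iset",
    records: Sequence[CompoundRecord] | None = None,
) -> list[dict]:
    """Recomputed-vs-published comparison, one dict per class.

    The affine-invariant statistics (r, r^2, s, q^2) carry absolute
    differences from the published cells; intercept/slope and F are
    reported without differences because the published predictor
    convention varies by class and F is hypersensitive to r^2 rounding.
    """
    printed = {
        (row["class"], row["method"]): row for row in load_table2_printed()
    }
    out = []
    for summ in reproduce_table2(records, method):
        ref = printed[(summ.compound_class, method)]
        rep = summ.report
        out.append(
            {
                "class": summ.compound_class,
                "method": method,
                "n": summ.n,
                "n_printed": ref["n"],
                "a": summ.model.a,
                "b": summ.model.b,
                "r": rep.r,
                "r2": rep.r2,
                "s": rep.s,
                "f": rep.f,
                "q2_cv": rep.q2_cv,
                "dr": abs(rep.r - ref["r"]),
                "dr2": abs(rep.r2 - ref["r2"]),
                "ds": abs(rep.s - ref["s"]),
                "dq2": abs(rep.q2_cv - ref["rcv2"]),
            }
        )
    return out


def write_table(records: Sequence[CompoundRecord], path, header: Sequence[str]) -> None:
    """Write records back in the packaged TSV dialect, byte-stable for
    records loaded from a packaged table (their original rows are kept)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(header))
        for rec in records:
            if not rec.raw_row:
                raise ValueError(f"record {rec.name!r} has no raw row to write")
            row = list(rec.raw_row)
            while row and row[-1] == "":
                row.pop()
            writer.writerow(row)
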