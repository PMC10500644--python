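"""Readers and writers for the pipeline's plain-text formats.

All formats are line-oriented text: FASTA for sequences (Biopython),
delimited tables for curves / shift ensembles / sample records (pandas,
delimiter sniffed between comma and tab), and two-column ppm/intensity
text for spectra.  Metadata rides in ``# key: value`` comment headers.
Readers reject ambiguous input loudly — a missing column or an unknown
unit is an error naming the offender, never a silent coercion.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dnpmetrics import DnpSampleRecord, derive_sensitivity
from .ensembleshift import ShiftEnsemble, Spectrum1D
from .errors import DataError
from .relaxfit import FitResult, RelaxationCurve
from .seqdesign import looks_like_nucleotide, translate_nucleotide


@dataclass
class FastaRecord:
    id: str
    sequence: str
    is_nucleotide: bool

    def as_protein(self) -> str:
        """The protein sequence, translating frame 1 if nucleotide."""
        return translate_nucleotide(self.sequence) if self.is_nucleotide else self.sequence


def read_fasta(path: str | Path, force_alphabet: str | None = None) -> list[FastaRecord]:
    """Parse FASTA; protein vs nucleotide auto-detected per record.

    ``force_alphabet`` ("protein" | "nucleotide") overrides detection for
    composition-biased sequences the heuristic would misread.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if force_alphabet not in (None, "protein", "nucleotide"):
        raise DataError(f"unknown alphabet override {force_alphabet!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise DataError(f"empty sequence for record {rec.id!r} in {path}")
        if force_alphabet is None:
            is_nt = looks_like_nucleotide(seq)
        else:
            is_nt = force_alphabet == "nucleotide"
        records.append(FastaRecord(id=rec.id, sequence=seq, is_nucleotide=is_nt))
    if not records:
        raise DataError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------- tables


def _read_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
    return meta


def _detect_sep(path: Path) -> str:
    """Delimiter from the first non-comment line: tab, comma, or whitespace."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if "\t" in line:
                return "\t"
            if "," in line:
                return ","
            return r"\s+"
    raise DataError(f"{path}: no data lines")


def _read_delimited(path: Path, **kwargs) -> pd.DataFrame:
    """Read CSV or TSV (delimiter detected); '#' lines are comments."""
    sep = _detect_sep(path)
    try:
        return pd.read_csv(path, sep=sep, engine="python", comment="#", **kwargs)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"cannot parse table {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}; "
                        f"found {list(df.columns)}")


def read_curve(path: str | Path) -> RelaxationCurve:
    """Read a relaxation curve table.

    Layout: ``# key: value`` metadata lines (kind, site, time_unit,
    time_convention, optionally j_modulated), then a delimited table with
    columns ``delay`` and ``intensity``.  ``time_convention: tau`` echo
    delays are doubled on read to total echo time.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    meta = _read_meta(path)
    df = _read_delimited(path)
    _require_columns(df, ["delay", "intensity"], path)
    kind = meta.get("kind", "saturation_recovery")
    unit = meta.get("time_unit", "s")
    convention = meta.get("time_convention", "total")
    if convention not in ("total", "tau"):
        raise DataError(f"{path}: unknown time_convention {convention!r}")
    delays = df["delay"].to_numpy(dtype=float)
    if kind == "hahn_echo" and convention == "tau":
        delays = delays * 2.0
    curve = RelaxationCurve(
        delays=delays,
        intensities=df["intensity"].to_numpy(dtype=float),
        kind=kind,
        site=meta.get("site", ""),
        time_unit=unit,
    )
    if meta.get("j_modulated", "").lower() in ("true", "1", "yes"):
        curve.ground_truth = (curve.ground_truth or {}) | {"j_modulated": True}
    return curve


def write_curve(path: str | Path, curve: RelaxationCurve) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind: {curve.kind}\n")
        if curve.site:
            fh.write(f"# site: {curve.site}\n")
        fh.write(f"# time_unit: {curve.time_unit}\n")
        fh.write("# time_convention: total\n")
        if curve.ground_truth and curve.ground_truth.get("model") == "j_modulated_echo":
            fh.write("# j_modulated: true\n")
        fh.write("delay,intensity\n")
        for t, y in zip(curve.delays, curve.intensities):
            fh.write(f"{float(t)!r},{float(y)!r}\n")


def read_spectrum(path: str | Path) -> Spectrum1D:
    """Two-column ppm/intensity text (whitespace, comma or tab separated)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    meta = _read_meta(path)
    try:
        df = pd.read_csv(path, sep=_detect_sep(path), engine="python", comment="#",
                         header=None, names=["ppm", "intensity"],
                         skip_blank_lines=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"cannot parse spectrum {path}: {exc}") from exc
    # tolerate an optional header row
    if df.iloc[0].map(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:]
    try:
        ppm = df["ppm"].to_numpy(dtype=float)
        intensity = df["intensity"].to_numpy(dtype=float)
    except ValueError as exc:
        raise DataError(f"non-numeric data in spectrum {path}: {exc}") from exc
    ref = None
    if "reference_name" in meta and "reference_ppm" in meta:
        ref = (meta["reference_name"], float(meta["reference_ppm"]))
    return Spectrum1D(ppm=ppm, intensity=intensity,
                      site=meta.get("site", ""), reference_peak=ref)


def write_spectrum(path: str | Path, spectrum: Spectrum1D) -> None:
    with open(path, "w") as fh:
        if spectrum.site:
            fh.write(f"# site: {spectrum.site}\n")
        if spectrum.reference_peak is not None:
            name, ppm = spectrum.reference_peak
            fh.write(f"# reference_name: {name}\n# reference_ppm: {ppm!r}\n")
        fh.write("# axis: ppm ascending (display convention is descending)\n")
        for x, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{float(x)!r}\t{float(y)!r}\n")


def read_shift_table(path: str | Path) -> ShiftEnsemble:
    """Per-frame shift table: one column per atom site, one row per frame."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = _read_delimited(path)
    if df.empty or df.shape[1] < 1:
        raise DataError(f"{path}: shift table has no data")
    try:
        shifts = {str(c): df[c].to_numpy(dtype=float) for c in df.columns}
    except ValueError as exc:
        raise DataError(f"{path}: non-numeric shift values: {exc}") from exc
    return ShiftEnsemble(shifts=shifts, provenance=str(path))


def write_shift_table(path: str | Path, ensemble: ShiftEnsemble) -> None:
    pd.DataFrame(ensemble.shifts).to_csv(path, index=False)


_SAMPLE_COLUMNS = [
    "sample", "radical", "concentration_mM", "T1_on_s", "T1_off_s",
    "T2_N_ms", "T2_CO_ms", "enhancement", "polarization_percent",
]


def read_sample_table(path: str | Path) -> list[DnpSampleRecord]:
    """Read a DNP sample-parameter table (TSV/CSV, one row per sample)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = _read_delimited(path)
    _require_columns(df, _SAMPLE_COLUMNS, path)

    def opt(v):
        return None if pd.isna(v) or v in ("-", "") else float(v)

    records = []
    for _, row in df.iterrows():
        t2 = {}
        if opt(row["T2_N_ms"]) is not None:
            t2["amide-N"] = float(row["T2_N_ms"])
        if opt(row["T2_CO_ms"]) is not None:
            t2["CO"] = float(row["T2_CO_ms"])
        radical = row["radical"]
        records.append(
            DnpSampleRecord(
                label=str(row["sample"]),
                radical=None if pd.isna(radical) or radical in ("-", "none", "") else str(radical),
                concentration_mM=float(row["concentration_mM"]),
                enhancement=float(row["enhancement"]),
                polarization=float(row["polarization_percent"]),
                T1_on_s=opt(row["T1_on_s"]),
                T1_off_s=opt(row["T1_off_s"]),
                t2_ms=t2,
            )
        )
    return records


def write_sample_table(
    path: str | Path, records: list[DnpSampleRecord], derived: bool = True
) -> None:
    """Write sample records as TSV; derived sensitivity appended as a new
    column, never overwriting the measured inputs."""
    rows = []
    for r in records:
        if derived:
            r = derive_sensitivity(r)
        rows.append({
            "sample": r.label,
            "radical": r.radical or "-",
            "concentration_mM": r.concentration_mM,
            "T1_on_s": "-" if r.T1_on_s is None else r.T1_on_s,
            "T1_off_s": "-" if r.T1_off_s is None else r.T1_off_s,
            "T2_N_ms": r.t2_ms.get("amide-N", "-"),
            "T2_CO_ms": r.t2_ms.get("CO", "-"),
            "enhancement": r.enhancement,
            "polarization_percent": r.polarization * 100.0,
            **({"sensitivity_per_sqrt_s": round(r.sensitivity, 4)} if derived else {}),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def fit_result_to_json(result: FitResult) -> str:
    return json.dumps(asdict(result), indent=2, sort_keys=True)


def write_fit_results(path: str | Path, results: dict[str, FitResult]) -> None:
    payload = {name: asdict(res) for name, res in sorted(results.items())}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_pairs_tsv(path: str | Path, pairs) -> None:
    from .seqdesign import pairs_to_records

    df = pd.DataFrame(pairs_to_records(pairs))
    if df.empty:
        df = pd.DataFrame(columns=["position", "pair", "labels", "site",
                                   "is_homopair", "region", "flags"])
    df.to_csv(path, sep="\t", index=False)


def buffer_round_trip(write_fn, read_fn, *args):  # pragma: no cover - helper
    buf = _io.StringIO()
    write_fn(buf, *args)
    buf.seek(0)
    return read_fn(buf)
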