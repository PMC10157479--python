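"""Waveform record I/O: CSV and a minimal WFDB-compatible subset.

CSV records are single-channel: a header row ``t,ecg_mv`` followed by one
row per sample (comma separator, ``.`` decimal).  The sampling rate is
recovered from the time column.

Multi-channel records use a minimal subset of the WFDB format: a text
``.hea`` header and an interleaved little-endian int32 ``.dat`` file
(WFDB format 32) with an ADC gain of 1e6 per mV, so round trips are exact
to 5e-7 mV.  A compression reference, when present, is stored as an
auxiliary 0/1 impulse channel named ``cc_onset`` whose nonzero samples
mark compression-cycle onsets.  Only records written by this module are
guaranteed to read back; the subset is documented here, not a general
WFDB parser.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import CompressionReference, EcgSegment, SegmentRole
from .exceptions import ConfigurationError, RecordIOError

_GAIN = 1_000_000.0  # ADC units per mV; int32 keeps +/-2147 mV of range
_FMT = 32
_CC_CHANNEL = "cc_onset"


def write_record(
    segment: EcgSegment,
    path: str | Path,
    format: str = "wfdb",
    ref: CompressionReference | None = None,
) -> Path:
    """Write a segment (and optional compression reference) to disk.

    ``path`` is the record stem for WFDB (``.hea``/``.dat`` appended) or the
    file path for CSV.  CSV cannot carry a reference channel.
    """
    path = Path(path)
    if format == "csv":
        if ref is not None:
            raise ConfigurationError("CSV records are single-channel; "
                                     "use wfdb format for a compression reference")
        df = pd.DataFrame({"t": segment.times, "ecg_mv": segment.samples})
        df.to_csv(path, index=False)
        return path
    if format != "wfdb":
        raise ConfigurationError(f"unknown record format: {format!r}")

    channels = [("ecg", segment.samples)]
    if ref is not None:
        impulse = np.zeros(segment.n)
        idx = np.round((ref.onset_times - segment.t0) * segment.fs).astype(int)
        idx = idx[(idx >= 0) & (idx < segment.n)]
        impulse[idx] = 1.0
        channels.append((_CC_CHANNEL, impulse))

    stem = path.with_suffix("")
    name = stem.name
    data = np.stack([np.round(c * _GAIN) for _, c in channels], axis=1)
    if np.any(np.abs(data) > np.iinfo(np.int32).max):
        raise RecordIOError(f"{path}: sample magnitude exceeds int32 ADC range")
    data = data.astype("<i4")

    lines = [f"{name} {len(channels)} {segment.fs:g} {segment.n}"]
    for ch_name, _ in channels:
        init = int(data[0, len(lines) - 1]) if segment.n else 0
        lines.append(f"{name}.dat {_FMT} {_GAIN:g}(0)/mV 32 0 {init} 0 0 {ch_name}")
    lines.append(f"# role={segment.role.value} subject={segment.subject_id or ''} "
                 f"t0={segment.t0:g}")
    stem.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    data.tofile(stem.with_suffix(".dat"))
    return stem.with_suffix(".hea")


def read_record(
    path: str | Path, format: str = "wfdb"
) -> tuple[EcgSegment, CompressionReference | None]:
    """Read a waveform record in the named format.

    Returns the ECG in mV at its native rate and, for WFDB records that
    carry a ``cc_onset`` channel, the reconstructed compression reference.
    """
    path = Path(path)
    if format == "csv":
        return _read_csv(path), None
    if format != "wfdb":
        raise ConfigurationError(f"unknown record format: {format!r}")
    return _read_wfdb(path)


def _read_csv(path: Path) -> EcgSegment:
    if not path.exists():
        raise RecordIOError(f"record not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV structure
        raise RecordIOError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise RecordIOError(f"{path}: expected columns t,ecg_mv")
    t = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    x = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    bad = np.flatnonzero(t.isna() | x.isna())
    if bad.size:
        raise RecordIOError(f"{path}: non-numeric value at data row {bad[0]}")
    t = t.to_numpy()
    if t.size < 2:
        raise RecordIOError(f"{path}: need at least 2 samples to infer rate")
    fs = 1.0 / float(np.median(np.diff(t)))
    return EcgSegment(samples=x.to_numpy(), fs=round(fs, 6), t0=float(t[0]))


def _read_wfdb(path: Path) -> tuple[EcgSegment, CompressionReference | None]:
    stem = path.with_suffix("") if path.suffix in {".hea", ".dat"} else path
    hea, dat = stem.with_suffix(".hea"), stem.with_suffix(".dat")
    if not hea.exists() or not dat.exists():
        raise RecordIOError(f"record not found: {stem}(.hea/.dat)")
    lines = [ln for ln in hea.read_text().splitlines() if ln.strip()]
    meta = {}
    for ln in lines:
        if ln.startswith("#"):
            for tok in ln[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    try:
        _, n_sig, fs, n_samp = lines[0].split()[:4]
        n_sig, fs, n_samp = int(n_sig), float(fs), int(n_samp)
        sig_lines = lines[1:1 + n_sig]
        gains, names = [], []
        for ln in sig_lines:
            toks = ln.split()
            gains.append(float(toks[2].split("(")[0]))
            names.append(toks[-1])
        raw = np.fromfile(dat, dtype="<i4").reshape(n_samp, n_sig)
    except (ValueError, IndexError) as exc:
        raise RecordIOError(f"{stem}: corrupt WFDB header or data ({exc})") from exc

    t0 = float(meta.get("t0", 0.0))
    role = SegmentRole(meta["role"]) if "role" in meta else SegmentRole.UNKNOWN
    subject = meta.get("subject") or None
    ecg = EcgSegment(samples=raw[:, 0] / gains[0], fs=fs, role=role,
                     subject_id=subject, t0=t0)
    ref = None
    if _CC_CHANNEL in names:
        j = names.index(_CC_CHANNEL)
        onsets = t0 + np.flatnonzero(raw[:, j] > gains[j] / 2) / fs
        if onsets.size >= 2:
            ref = CompressionReference(onset_times=onsets, fs=fs)
    return ecg, ref


def save_dataset(splits: dict, out_dir: str | Path) -> Path:
    """Serialise build_dataset splits: WFDB records plus a CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for split, pairs in splits.items():
        for i, pair in enumerate(pairs):
            stem_c = out_dir / f"{split}_{i:05d}_cvf"
            stem_u = out_dir / f"{split}_{i:05d}_uvf"
            write_record(pair.corrupted, stem_c, "wfdb", ref=pair.cc_ref)
            write_record(pair.uncorrupted, stem_u, "wfdb")
            rows.append({"split": split, "index": i,
                         "subject_id": pair.subject_id,
                         "snr_db": pair.snr_db, "amsa_true": pair.amsa_true,
                         "corrupted_record": stem_c.name,
                         "uncorrupted_record": stem_u.name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"


def load_dataset(data_dir: str | Path) -> dict:
    """Load a save_dataset directory back into split -> [SegmentPair]."""
    from .core import SegmentPair

    data_dir = Path(data_dir)
    manifest_path = data_dir / "manifest.csv"
    if not manifest_path.exists():
        raise RecordIOError(f"dataset manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    splits: dict[str, list] = {}
    for row in manifest.itertuples():
        corrupted, ref = read_record(data_dir / row.corrupted_record, "wfdb")
        uncorrupted, _ = read_record(data_dir / row.uncorrupted_record, "wfdb")
        snr = None if pd.isna(row.snr_db) else float(row.snr_db)
        subj = None if pd.isna(row.subject_id) else str(row.subject_id)
        pair = SegmentPair(corrupted=corrupted, uncorrupted=uncorrupted,
                           amsa_true=float(row.amsa_true), subject_id=subj,
                           snr_db=snr, cc_ref=ref)
        splits.setdefault(row.split, []).append(pair)
    return splits
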