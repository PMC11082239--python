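"""Multichannel WAVE input/output, the clip filename grammar, and manifests.

Raw recordings enter this toolkit as uncompressed RIFF/WAVE files (IEEE
float-32 or 16/24/32-bit integer PCM).  Vendor acquisition formats such as
TDMS are expected to be converted to WAVE upstream (the vendor's own Python
tooling does this in one line); that conversion is deliberately outside this
package.

Extracted clips are written as IEEE float-32 WAVE files named

    <YYYY-MM-DD>_<Genus>_<species>_<NNNNNN>.wav

i.e. recording date, full scientific species name (spaces replaced by
underscores), and a zero-padded running index that guarantees uniqueness
within an extraction run.  A manifest — one CSV row per clip with path,
species, date, duration, optional level statistic and optional split label —
is the hand-off point between extraction, level summaries and dataset
splitting.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import re
import struct
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Recording",
    "Clip",
    "WaveFormatError",
    "read_wave",
    "write_clip",
    "format_clip_name",
    "parse_clip_name",
    "data_payload_bytes",
    "MANIFEST_COLUMNS",
    "build_manifest",
    "read_manifest",
    "write_manifest",
]

MANIFEST_COLUMNS = ["path", "species", "date", "duration_ms", "spl_db", "split"]

_CLIP_NAME_RE = re.compile(
    r"^(?P<date>\d{4}-\d{2}-\d{2})_(?P<species>[A-Za-z][A-Za-z.\-]*(?:_[A-Za-z.\-]+)+)"
    r"_(?P<index>\d{6})\.wav$"
)


class WaveFormatError(ValueError):
    """Raised for unreadable, truncated or unsupported WAVE files."""


@dataclasses.dataclass
class Recording:
    """A multichannel audio recording with provenance metadata.

    ``samples`` is a ``(n_channels, n_samples)`` float array of dimensionless
    amplitudes on a [-1, 1] full-scale convention.  ``date`` and ``species``
    label the recording session; ``source_id`` identifies the originating
    file.
    """

    samples: np.ndarray
    rate: int
    date: _dt.date | None = None
    species: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_samples) array")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.samples.shape[0] < 1:
            raise ValueError("a recording needs at least one channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording amplitudes must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclasses.dataclass
class Clip:
    """A fixed-length multichannel excerpt of a recording.

    ``start_offset`` is the sample index of the clip's first sample in the
    parent recording, on the post-resampling timeline.  ``index`` is the
    running integer used in the output filename.
    """

    samples: np.ndarray
    rate: int
    start_offset: int
    date: _dt.date | None = None
    species: str = ""
    index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_samples) array")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("clip amplitudes must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.rate


def read_wave(path: str | Path) -> Recording:
    """Read an uncompressed WAVE file into a :class:`Recording`.

    Accepts IEEE float-32/64 and 8/16/24/32-bit integer PCM.  Integer PCM is
    rescaled to [-1, 1] by the full-scale value of its width (e.g. 16384 in
    int16 becomes 0.5).  Channels are returned de-interleaved.  Compressed or
    otherwise unsupported format tags (e.g. mu-law) raise
    :class:`WaveFormatError`.
    """
    path = Path(path)
    if not path.is_file():
        raise WaveFormatError(f"no such file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise WaveFormatError(f"unsupported format in {path.name}: {exc}") from exc
    except Exception as exc:  # truncated/garbage containers
        raise WaveFormatError(f"unreadable WAVE file {path.name}: {exc}") from exc
    if data.size == 0:
        raise WaveFormatError(f"empty WAVE file: {path.name}")
    if data.ndim == 1:
        data = data[:, np.newaxis]
    if data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        # scipy returns 24-bit PCM left-justified in int32, same scale
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise WaveFormatError(f"unsupported sample dtype {data.dtype} in {path.name}")
    name_meta = _try_parse_clip_name(path.name)
    date, species = (name_meta[0], name_meta[1]) if name_meta else (None, "")
    return Recording(
        samples=samples.T, rate=int(rate), date=date, species=species,
        source_id=path.name,
    )


def format_clip_name(date: _dt.date, species: str, index: int) -> str:
    """Compose the clip filename from its metadata.

    The species name has internal whitespace replaced by underscores; the
    index is zero-padded to six digits.
    """
    species_part = "_".join(species.split())
    if not species_part or "_" not in species_part:
        raise ValueError(
            f"species must be a full scientific name (genus + epithet), got {species!r}"
        )
    if not 0 <= index <= 999999:
        raise ValueError(f"index out of range for 6-digit field: {index}")
    return f"{date.isoformat()}_{species_part}_{index:06d}.wav"


def parse_clip_name(filename: str) -> tuple[_dt.date, str, int]:
    """Parse ``<date>_<Genus>_<species>_<NNNNNN>.wav`` into its components."""
    m = _CLIP_NAME_RE.match(Path(filename).name)
    if m is None:
        raise ValueError(
            f"filename {filename!r} does not match "
            "'<YYYY-MM-DD>_<Genus>_<species>_<NNNNNN>.wav'"
        )
    try:
        date = _dt.date.fromisoformat(m.group("date"))
    except ValueError as exc:
        raise ValueError(f"invalid date in filename {filename!r}: {exc}") from exc
    species = m.group("species").replace("_", " ")
    return date, species, int(m.group("index"))


def _try_parse_clip_name(filename: str) -> tuple[_dt.date, str, int] | None:
    try:
        return parse_clip_name(filename)
    except ValueError:
        return None


def write_clip(clip: Clip, out_dir: str | Path) -> Path:
    """Write a clip as an interleaved IEEE float-32 WAVE file.

    The filename follows the clip grammar, so the clip must carry a date and
    a full species name.  Returns the written path.
    """
    if clip.n_samples == 0:
        raise ValueError("refusing to write an empty clip")
    if clip.date is None:
        raise ValueError("clip has no recording date; cannot compose filename")
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise NotADirectoryError(f"output directory does not exist: {out_dir}")
    name = format_clip_name(clip.date, clip.species, clip.index)
    path = out_dir / name
    wavfile.write(str(path), int(clip.rate), clip.samples.T.astype(np.float32))
    return path


def data_payload_bytes(path: str | Path) -> int:
    """Return the size in bytes of a WAVE file's ``data`` chunk payload."""
    with open(path, "rb") as fh:
        riff, _size, wave_id = struct.unpack("<4sI4s", fh.read(12))
        if riff != b"RIFF" or wave_id != b"WAVE":
            raise WaveFormatError(f"not a RIFF/WAVE file: {path}")
        while True:
            header = fh.read(8)
            if len(header) < 8:
                raise WaveFormatError(f"no data chunk found in {path}")
            chunk_id, chunk_size = struct.unpack("<4sI", header)
            if chunk_id == b"data":
                return chunk_size
            fh.seek(chunk_size + (chunk_size % 2), 1)


def build_manifest(clip_dir: str | Path) -> pd.DataFrame:
    """Index a directory of clips into a manifest DataFrame.

    Lists exactly the ``.wav`` files present, each once, sorted by name.
    Metadata comes from the filename grammar; duration from the WAVE header.
    """
    clip_dir = Path(clip_dir)
    rows = []
    for path in sorted(clip_dir.glob("*.wav")):
        date, species, _index = parse_clip_name(path.name)
        rec = read_wave(path)
        rows.append(
            {
                "path": str(path),
                "species": species,
                "date": date.isoformat(),
                "duration_ms": 1000.0 * rec.n_samples / rec.rate,
                "spl_db": np.nan,
                "split": "",
            }
        )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"path": str, "species": str, "date": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    if df["path"].duplicated().any():
        dupes = df.loc[df["path"].duplicated(), "path"].tolist()
        raise ValueError(f"duplicate manifest paths: {dupes[:5]}")
    df["split"] = df["split"].fillna("")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, MANIFEST_COLUMNS].to_csv(path, index=False)
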