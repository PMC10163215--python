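"""CSV/config readers and writers for the project's file dialects.

All writers emit UTF-8, '.'-decimal, fixed column order and ``%.12g`` float
formatting, so identical inputs give byte-identical files and numeric
round-trips are lossless to 12 significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .qcmd import QcmdTrace
from .spr import Sensorgram, InjectionPhase

__all__ = [
    "ParseError",
    "read_sensorgram_csv",
    "write_sensorgram_csv",
    "read_qcmd_csv",
    "write_qcmd_csv",
    "write_fit_report_csv",
    "write_call_report_csv",
    "write_cohort_manifest_csv",
    "StudyConfig",
]

_FLOAT = "%.12g"

SENSORGRAM_HEADER = "time_s,response_RU,phase"
QCMD_HEADER = "time_s,overtone,delta_f_Hz,delta_D_1e-6"
FIT_REPORT_HEADER = "sample_id,probe_id,ka,kd,Kd,Ka,se_ka,se_kd,rss,converged"
CALL_REPORT_HEADER = "sample_id,assay,overall_slope,reference_slope,relative_diff,call"
MANIFEST_HEADER = "sample_id,panel,true_status,ka_true,kd_true,softness,seed"


class ParseError(ValueError):
    """Raised with a line number on malformed dialect files."""


def write_sensorgram_csv(sensorgram: Sensorgram, path: str | Path) -> None:
    lines = [SENSORGRAM_HEADER]
    for t, r, phase in zip(sensorgram.time, sensorgram.response, sensorgram.phase_labels):
        lines.append(f"{_FLOAT % t},{_FLOAT % r},{phase}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_sensorgram_csv(path: str | Path, metadata: dict | None = None) -> Sensorgram:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != SENSORGRAM_HEADER:
        raise ParseError(f"{path}:1: expected header '{SENSORGRAM_HEADER}'")
    time, response, phases = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        try:
            time.append(float(parts[0]))
            response.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        phase = parts[2].strip()
        if phase not in InjectionPhase.KINDS:
            raise ParseError(f"{path}:{lineno}: unknown phase {phase!r}")
        phases.append(phase)
    try:
        return Sensorgram(
            np.array(time), np.array(response), tuple(phases), metadata=dict(metadata or {})
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_qcmd_csv(trace: QcmdTrace, path: str | Path) -> None:
    lines = [QCMD_HEADER]
    for n in trace.overtones:
        for t, f, d in zip(trace.time, trace.delta_f[n], trace.delta_D[n]):
            lines.append(f"{_FLOAT % t},{n},{_FLOAT % f},{_FLOAT % d}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_qcmd_csv(path: str | Path, metadata: dict | None = None) -> QcmdTrace:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != QCMD_HEADER:
        raise ParseError(f"{path}:1: expected header '{QCMD_HEADER}'")
    rows: dict[int, list[tuple[float, float, float]]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        try:
            t, n, f, d = float(parts[0]), int(parts[1]), float(parts[2]), float(parts[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        rows.setdefault(n, []).append((t, f, d))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    times = None
    delta_f, delta_D = {}, {}
    for n, series in rows.items():
        t = np.array([s[0] for s in series])
        if times is None:
            times = t
        elif t.shape != times.shape or not np.allclose(t, times):
            raise ParseError(f"{path}: overtone {n} has a different time grid")
        delta_f[n] = np.array([s[1] for s in series])
        delta_D[n] = np.array([s[2] for s in series])
    return QcmdTrace(times, delta_f, delta_D, metadata=dict(metadata or {}))


def write_fit_report_csv(rows: list[dict], path: str | Path) -> None:
    """Rows need keys sample_id, probe_id, ka, kd, Kd, Ka, se_ka, se_kd, rss, converged."""
    lines = [FIT_REPORT_HEADER]
    for r in rows:
        lines.append(
            ",".join(
                [
                    str(r["sample_id"]),
                    str(r["probe_id"]),
                    *(_FLOAT % r[k] for k in ("ka", "kd", "Kd", "Ka", "se_ka", "se_kd", "rss")),
                    "true" if r["converged"] else "false",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_call_report_csv(rows: list[dict], path: str | Path) -> None:
    lines = [CALL_REPORT_HEADER]
    for r in rows:
        lines.append(
            ",".join(
                [
                    str(r["sample_id"]),
                    str(r["assay"]),
                    _FLOAT % r.get("overall_slope", float("nan")),
                    _FLOAT % r.get("reference_slope", float("nan")),
                    _FLOAT % r.get("relative_diff", float("nan")),
                    str(r["call"]),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_cohort_manifest_csv(samples, path: str | Path, seed: int) -> None:
    lines = [MANIFEST_HEADER]
    for s in samples:
        lines.append(
            ",".join(
                [
                    s.sample_id,
                    s.mutation_panel,
                    s.true_status,
                    _FLOAT % s.params.ka,
                    _FLOAT % s.params.kd,
                    _FLOAT % s.layer_softness,
                    str(seed),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclasses.dataclass
class StudyConfig:
    """Serializable run configuration (YAML or JSON)."""

    seed: int = 0
    n_carriers: int = 17
    n_noncarriers: int = 5
    panel: str = "5382insC"
    noise_sd: float = 0.5
    noise_sd_f: float = 0.05
    noise_sd_D: float = 0.002
    threshold_factor: float = 10.0
    tol_positive: float = 0.15
    tol_ambiguous: float = 0.35
    concentration: float = 100e-9
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.threshold_factor < 1:
            raise ValueError("threshold_factor must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text, encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    @property
    def digest(self) -> str:
        """Stable hash of the configuration, for provenance records."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
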