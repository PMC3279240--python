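"""Analysis configuration, per-image symptom reports, batch running and export.

This is the glue that turns the five pipeline functions into a batch tool:
an :class:`AnalysisConfig` collects every user-tunable parameter with a
documented default, :func:`run` applies the selected pipelines to a list of
images producing one :class:`SymptomReport` each, and :func:`export` writes
the reports as JSON (nested) or CSV (one flat row per image).  Reports embed
the parameters and a configuration hash, so any number in a report can be
reproduced exactly from the report alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import chlorosis as _chlorosis
from . import deformation as _deformation
from . import mosaic as _mosaic
from . import necrosis as _necrosis
from . import white_spots as _white_spots
from .imaging_core import LeafQuantError, RgbImage, read_rgb
from .morphology import StructuringElement

__all__ = ["AnalysisConfig", "SymptomReport", "run", "export", "load_reports", "SYMPTOMS"]

log = logging.getLogger("leafquant")

SYMPTOMS = ("chlorosis", "necrosis", "deformation", "white_spots", "mosaic")


def parse_se(spec: str) -> StructuringElement:
    """Parse a structuring-element spec: ``box:N``, ``disk:R``, ``cross:N``
    or ``@path`` pointing at a 0/1 text grid."""
    if spec.startswith("@"):
        return StructuringElement.from_text(Path(spec[1:]).read_text())
    kind, _, arg = spec.partition(":")
    try:
        n = int(arg)
        return {"box": StructuringElement.box,
                "disk": StructuringElement.disk,
                "cross": StructuringElement.cross}[kind](n)
    except (KeyError, ValueError):
        raise ValueError(f"bad structuring element spec {spec!r}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Every tunable parameter of the five pipelines, with defaults.

    Thresholds are fractions of the channel maximum so the same configuration
    works at 8- and 10-bit working depth.
    """

    bit_depth: int = 8
    t_leaf: float = 0.80  #: blue-channel leaf/background threshold (fraction)
    t_necro: float = 0.35  #: green-channel necrosis threshold (fraction)
    t_spot: float = 0.80  #: blue-channel bright threshold for spots (fraction)
    se_necrosis: str = "box:3"
    se_mosaic: str = "disk:4"
    canny_sigma: float = 1.4
    canny_lo: float = 0.1  #: fraction of the max gradient magnitude
    canny_hi: float = 0.25
    connectivity: int = 8
    masked_chlorosis: bool = True  #: quadrant means over leaf pixels only
    centroid_masked: bool = False  #: restrict the centroid to the leaf mask
    hat_combine: str = "additive"  #: or "sequential"
    perimeter_estimator: str = "corner"  #: or "chain" / "raw"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_file(self, path) -> None:
        lines = [f"{k}={v}" for k, v in sorted(self.to_dict().items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cls, key)
            if isinstance(default, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


@dataclass
class SymptomReport:
    """One analyzed image: results per requested symptom, plus provenance."""

    image: str
    config_hash: str
    results: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "image": self.image,
            "config_hash": self.config_hash,
            "results": self.results,
            "warnings": self.warnings,
            "errors": self.errors,
        }


def _analyze_one(img: RgbImage, symptoms, config: AnalysisConfig, backlit: bool, report):
    maxv = img.max_value
    for symptom in symptoms:
        t0 = time.perf_counter()
        try:
            if symptom == "chlorosis":
                res = _chlorosis.quantify_chlorosis(
                    img,
                    masked=config.masked_chlorosis,
                    centroid_masked=config.centroid_masked,
                    t_leaf=config.t_leaf * maxv,
                )
            elif symptom == "necrosis":
                res = _necrosis.quantify_necrosis(
                    img,
                    t_necro=config.t_necro * maxv,
                    t_leaf=config.t_leaf * maxv,
                    se=parse_se(config.se_necrosis),
                    connectivity=config.connectivity,
                )
            elif symptom == "deformation":
                res = _deformation.quantify_deformation(
                    img, t_leaf=config.t_leaf * maxv, estimator=config.perimeter_estimator
                )
            elif symptom == "white_spots":
                res = _white_spots.quantify_white_spots(
                    img, t=config.t_spot * maxv, connectivity=config.connectivity
                )
            elif symptom == "mosaic":
                if not backlit:
                    report.warnings.append(
                        "mosaic skipped: image not flagged as back-lit (--backlit)"
                    )
                    continue
                res = _mosaic.quantify_mosaic(
                    img,
                    se=parse_se(config.se_mosaic),
                    sigma=config.canny_sigma,
                    edge_lo=config.canny_lo,
                    edge_hi=config.canny_hi,
                    t_leaf=config.t_leaf * maxv,
                    combine=config.hat_combine,
                )
            else:
                raise ValueError(f"unknown symptom {symptom!r}")
        except LeafQuantError as exc:
            report.errors[symptom] = str(exc)
            continue
        dt = time.perf_counter() - t0
        report.timings_s[symptom] = dt
        log.info("%s: %s done in %.3f s", report.image, symptom, dt)
        d = dataclasses.asdict(res)
        d.pop("params", None)
        d["params"] = res.params if hasattr(res, "params") else {}
        if symptom == "chlorosis":
            d = {
                "region_means": list(res.region_means),
                "l_counts": list(res.l_counts),
                "rn": res.rn,
                "rdiff": res.rdiff,
                "centroid": [res.centroid.cx, res.centroid.cy],
            }
        report.results[symptom] = d


def run(
    images,
    symptoms=SYMPTOMS,
    config: AnalysisConfig | None = None,
    backlit: bool = False,
    names=None,
) -> list[SymptomReport]:
    """Run the selected pipelines over a batch of images.

    ``images`` may be file paths or in-memory :class:`RgbImage` objects.
    Per-image failures (unreadable file, no leaf found) are recorded in the
    report and the batch continues.
    """
    if config is None:
        config = AnalysisConfig()
    symptoms = tuple(symptoms)
    for s in symptoms:
        if s not in SYMPTOMS:
            raise ValueError(f"unknown symptom {s!r}; choose from {SYMPTOMS}")
    reports = []
    cfg_hash = config.hash()
    for idx, item in enumerate(images):
        if isinstance(item, RgbImage):
            name = names[idx] if names else f"image_{idx:03d}"
            img = item
        else:
            name = str(item)
            img = None
        report = SymptomReport(image=name, config_hash=cfg_hash)
        if img is None:
            try:
                img = read_rgb(item, bit_depth=config.bit_depth)
            except Exception as exc:  # unreadable file
                report.errors["read"] = str(exc)
                reports.append(report)
                continue
        _analyze_one(img, symptoms, config, backlit, report)
        reports.append(report)
    return reports


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        elif isinstance(v, (list, tuple)):
            out[key] = json.dumps(list(v))
        else:
            out[key] = v
    return out


def export(reports, path, format: str = "json") -> None:
    """Write reports to ``path`` as nested JSON or one-flat-row-per-image CSV."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps([r.to_dict() for r in reports], indent=2) + "\n")
    elif format == "csv":
        import pandas as pd

        rows = [_flatten(r.to_dict()) for r in reports]
        frame = pd.DataFrame(rows)
        frame = frame.reindex(sorted(frame.columns), axis=1)  # stable column order
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown export format {format!r}")


def load_reports(path) -> list[dict]:
    """Read back a JSON export (round-trips :meth:`SymptomReport.to_dict`)."""
    return json.loads(Path(path).read_text())
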