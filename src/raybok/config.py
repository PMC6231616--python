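"""Structured run configuration.

One nested configuration object covers every stage — enhancement parameters,
bag-of-keypoints feature settings, random-forest settings, the experiment
matrix (input modes x schemes), I/O paths and the master seed.  Defaults are
the reference parameter values of the method; the object round-trips through
YAML so runs are reproducible from a single file.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .classify import RfConfig
from .enhancement import ClaheParams, NlmParams, PadParams, INPUT_MODES
from .irma import SCHEMES

__all__ = ["FeatureConfig", "ExperimentConfig", "IoConfig", "RunConfig"]


@dataclass(frozen=True)
class FeatureConfig:
    """Bag-of-keypoints settings (see :class:`~raybok.features.BagOfKeypointsExtractor`)."""

    step: int = 4
    bin_sizes: tuple[int, ...] = (4, 6, 8, 10)
    k: int = 1000
    per_image_cap: int = 1000
    pca_dim: int = 100
    kmeans_max_iter: int = 20
    assign: str = "kdtree"

    def extractor_params(self) -> dict:
        return {
            "step": self.step,
            "bin_sizes": tuple(self.bin_sizes),
            "k": self.k,
            "per_image_cap": self.per_image_cap,
            "pca_dim": self.pca_dim,
            "kmeans_max_iter": self.kmeans_max_iter,
            "assign": self.assign,
        }


@dataclass(frozen=True)
class ExperimentConfig:
    modes: tuple[str, ...] = INPUT_MODES
    schemes: tuple[str, ...] = SCHEMES


@dataclass(frozen=True)
class IoConfig:
    image_dir: str = "images"
    labels_csv: str = "images/labels.csv"
    out_dir: str = "out"


@dataclass(frozen=True)
class RunConfig:
    clahe: ClaheParams = field(default_factory=ClaheParams)
    nlm: NlmParams = field(default_factory=NlmParams)
    pad: PadParams = field(default_factory=PadParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    rf: RfConfig = field(default_factory=RfConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    io: IoConfig = field(default_factory=IoConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(repr(sorted(self.to_dict().items())).encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return obj

        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def _build(dc_type, section):
            kwargs = {}
            for f in fields(dc_type):
                if f.name in section:
                    v = section[f.name]
                    if isinstance(v, list):
                        v = tuple(v)
                    kwargs[f.name] = v
            return dc_type(**kwargs)

        return cls(
            clahe=_build(ClaheParams, _section(data, "clahe")),
            nlm=_build(NlmParams, _section(data, "nlm")),
            pad=_build(PadParams, _section(data, "pad")),
            features=_build(FeatureConfig, _section(data, "features")),
            rf=_build(RfConfig, _section(data, "rf")),
            experiment=_build(ExperimentConfig, _section(data, "experiment")),
            io=_build(IoConfig, _section(data, "io")),
            seed=int(data.get("seed", 0)),
        )


def _section(data: dict, name: str) -> dict:
    sec = data.get(name, {})
    if sec is None:
        return {}
    if "num_tiles" in sec and isinstance(sec["num_tiles"], list):
        sec = {**sec, "num_tiles": tuple(sec["num_tiles"])}
    if "out_range" in sec and isinstance(sec.get("out_range"), list):
        sec = {**sec, "out_range": tuple(sec["out_range"])}
    return sec
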