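"""Packaged reference tables: mobility assays, genomic Ty1 content, probe
coordinates and the Ty1-H3 region annotation defaults."""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .seqtools import RegionAnnotation

__all__ = [
    "load_mobility_his3ai",
    "load_mobility_neoai",
    "load_mobility_populated",
    "load_ty1_content",
    "load_gag_probes",
    "load_regions",
]


def _path(name: str):
    return resources.files("tyland.data") / name


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_path(name)) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_mobility_his3ai() -> pd.DataFrame:
    """his3-AI reporter frequencies (x 1e-6) for seven S. cerevisiae strains."""
    return _read_tsv("mobility_his3ai.tsv")


def load_mobility_neoai() -> pd.DataFrame:
    """neo-AI reporter frequencies (x 1e-7) for three S. paradoxus strains."""
    return _read_tsv("mobility_neoai.tsv")


def load_mobility_populated() -> pd.DataFrame:
    """Native vs Ty1-populated mobility for three permissive strains."""
    return _read_tsv("mobility_populated.tsv")


def load_ty1_content() -> pd.DataFrame:
    """Per-strain genomic Ty1 structural-class and gag-type counts."""
    return _read_tsv("ty1_content.tsv")


def load_gag_probes() -> pd.DataFrame:
    """gag probe coordinates on the Ty1-H3 and Ty2-917 reference elements."""
    return _read_tsv("gag_probes.tsv")


def load_regions(path=None) -> RegionAnnotation:
    """Ty1-H3 region annotation (packaged defaults or a user YAML)."""
    if path is None:
        with resources.as_file(_path("regions_ty1h3.yaml")) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return RegionAnnotation.from_dict(raw)
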