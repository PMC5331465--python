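"""Campaign configuration files.

A campaign config is YAML with sections ``model`` / ``params`` / ``plan``
/ ``library`` / ``effects`` / ``sampling``; every section is optional and
falls back to the package defaults, so a minimal scan config is just a
model and a list of positions.  Example::

    model:    {lam: 40.0, dG0: 2.0, k: 20.0}
    params:   {alpha: 0.0, h12: 0.0}
    plan:     {n_replicas: 4, md_length_ns: 8.0,
               snapshot_interval_ns: 1.0, discard_initial_ns: 2.0,
               master_seed: 1}
    library:  {type: alanine_scan,
               positions: [[93, L], [94, T]], exclusions: []}
    effects:  {shifts: {L93A: [-4.0, 0.0]}, epistasis: {"93,164": -1.5},
               noise_sd: 1.5, master_seed: 1}
    sampling: {n_steps_per_window: 4000}
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import yaml

from .campaign import ProtocolPlan, SurrogateTaskRunner
from .core import EVBParameters
from .errors import InvalidInputError
from .surrogate import EffectModel, SurrogateModel
from .variants import (
    AMINO_ACIDS,
    Variant,
    alanine_scan_library,
    combinatorial_library,
    parse_variant,
    site_saturation_library,
)

__all__ = ["load_config", "CampaignConfig"]


class CampaignConfig:
    """Materialized campaign objects built from one YAML document."""

    def __init__(self, raw: dict):
        self.raw = raw
        self.model = self._model(raw.get("model", {}))
        self.params = self._params(raw.get("params", {}))
        self.plan = ProtocolPlan(**raw.get("plan", {}))
        self.effects = self._effects(raw.get("effects", {}))
        self.n_steps_per_window = int(
            raw.get("sampling", {}).get("n_steps_per_window", 4000))

    @staticmethod
    def _model(sec: dict) -> SurrogateModel:
        if "lam" in sec:
            return SurrogateModel.from_targets(
                lam=float(sec["lam"]), dG0=float(sec.get("dG0", 0.0)),
                k=float(sec.get("k", 20.0)),
                temperature=float(sec.get("temperature", 300.0)),
            )
        return SurrogateModel(**sec)

    @staticmethod
    def _params(sec: dict) -> EVBParameters:
        return EVBParameters(
            alpha=float(sec.get("alpha", 0.0)),
            h12_const=float(sec.get("h12", sec.get("h12_const", 0.0))),
            temperature=float(sec.get("temperature", 300.0)),
        )

    @staticmethod
    def _effects(sec: dict) -> EffectModel:
        shifts = {k: (float(v[0]), float(v[1]))
                  for k, v in (sec.get("shifts") or {}).items()}
        epistasis = {}
        for key, val in (sec.get("epistasis") or {}).items():
            p, q = (int(x) for x in str(key).split(","))
            epistasis[tuple(sorted((p, q)))] = float(val)
        return EffectModel(
            shifts=shifts, epistasis=epistasis,
            noise_sd=float(sec.get("noise_sd", 1.5)),
            master_seed=int(sec.get("master_seed", 0)),
        )

    def library(self) -> List[Variant]:
        sec = self.raw.get("library", {})
        kind = sec.get("type", "variants")
        include_wt = bool(sec.get("include_wt", True))
        if kind == "alanine_scan":
            positions = [(int(p), str(a)) for p, a in sec["positions"]]
            lib = alanine_scan_library(
                positions, set(sec.get("exclusions", []) or []))
        elif kind == "site_saturation":
            lib = site_saturation_library(
                int(sec["position"]), str(sec["wt_aa"]),
                sec.get("alphabet") or AMINO_ACIDS,
            )
        elif kind == "combinatorial":
            choices = {
                int(pos): (str(val[0]), [str(r) for r in val[1]])
                for pos, val in sec["choices"].items()
            }
            lib = combinatorial_library(choices)
        elif kind == "variants":
            lib = [parse_variant(v) for v in sec.get("variants", [])]
        else:
            raise InvalidInputError(f"unknown library type {kind!r}")
        if include_wt:
            lib = [Variant()] + [v for v in lib if not v.is_wild_type]
        return lib

    def runner(self) -> SurrogateTaskRunner:
        return SurrogateTaskRunner(
            base_model=self.model, effects=self.effects,
            params=self.params,
            n_steps_per_window=self.n_steps_per_window,
        )


def load_config(path) -> CampaignConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return CampaignConfig(raw)
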