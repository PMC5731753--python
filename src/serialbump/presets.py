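"""Named model presets bundling network, plasticity, reset and adaptation.

Variants:

- ``model1``: fixed synapses, full reset (-0.08 nA) — the classical
  persistent-activity attractor.
- ``model2``: fixed synapses, weakened reset (-0.00925 nA, an 88.4%
  reduction) so a residual bump leaks into the inter-trial interval.
- ``model2_noreset``: reset current 0 nA; the bump persists unabated.
- ``model2_adaptation``: activity-leak model with the repulsive
  sensory-adaptation shift applied to the second cue.
- ``model3``: plastic synapses (augmentation + depression) with broad
  tuning (sigma=50°), coupling balanced for persistent firing, full reset.
- ``model3_adaptation``: plastic synapses with the adaptation-variant
  plasticity constants (tau_F=3.8 s, p=0.006, x=0.014, y=0.986) and the
  sensory-adaptation input shift.
- ``model3_narrow``: plastic synapses with narrow neuronal tuning
  (sigma=30°), coupling balanced the same way.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import yaml

from .ring_network import NetworkParams, PlasticityParams
from .task_protocol import AdaptationModel, ResetPolicy, StimulusParams

__all__ = ["ModelPreset", "PRESET_NAMES", "get_preset", "preset_to_yaml", "preset_from_yaml"]


@dataclass(frozen=True)
class ModelPreset:
    name: str
    net: NetworkParams
    plasticity: Optional[PlasticityParams]
    stim: StimulusParams
    reset: ResetPolicy
    adaptation: Optional[AdaptationModel]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "net": asdict(self.net),
            "plasticity": asdict(self.plasticity) if self.plasticity else None,
            "stim": asdict(self.stim),
            "reset": asdict(self.reset),
            "adaptation": asdict(self.adaptation) if self.adaptation else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelPreset":
        return cls(
            name=d["name"],
            net=NetworkParams(**d["net"]),
            plasticity=PlasticityParams(**d["plasticity"]) if d.get("plasticity") else None,
            stim=StimulusParams(**d["stim"]),
            reset=ResetPolicy(**d["reset"]),
            adaptation=AdaptationModel(**d["adaptation"]) if d.get("adaptation") else None,
        )


_FIXED_NET = NetworkParams()  # sigma_conn=43.2, J_plus=2.2

# The broad- and narrow-tuning couplings are calibrated so each network
# sits at the same fractional margin above its bump-ignition threshold as
# the fixed-synapse network (J+ = 2.2 vs a measured threshold of 2.185,
# i.e. kappa = 1.0069).  Measured thresholds (1-s cue at 0.02 nA, bump
# amplitude > 5 Hz after a 10-s delay, plasticity active): 1.997 nA at
# sigma = 50 deg and 2.799 nA at sigma = 30 deg.  This "balanced for
# persistent firing" criterion fixes the couplings from bump persistence
# alone; see docs/methods.md for the calibration procedure.
_PLASTIC_NET = NetworkParams(sigma_conn=50.0, J_plus=2.0105)
_NARROW_NET = NetworkParams(sigma_conn=30.0, J_plus=2.8180)

_PLAST_DEFAULT = PlasticityParams()
_PLAST_ADAPT = PlasticityParams(
    tau_F=3.8, p_release=0.006, x_ceiling=0.014, y_base=0.986
)

_FULL_RESET = ResetPolicy(reset_current=-0.08)
_LEAK_RESET = ResetPolicy(reset_current=-0.00925)
_NO_RESET = ResetPolicy(reset_current=0.0)

_ADAPT = AdaptationModel()


def _build(name: str) -> ModelPreset:
    stim = StimulusParams()
    if name == "model1":
        return ModelPreset(name, _FIXED_NET, None, stim, _FULL_RESET, None)
    if name == "model2":
        return ModelPreset(name, _FIXED_NET, None, stim, _LEAK_RESET, None)
    if name == "model2_noreset":
        return ModelPreset(name, _FIXED_NET, None, stim, _NO_RESET, None)
    if name == "model2_adaptation":
        return ModelPreset(name, _FIXED_NET, None, stim, _LEAK_RESET, _ADAPT)
    if name == "model3":
        return ModelPreset(name, _PLASTIC_NET, _PLAST_DEFAULT, stim, _FULL_RESET, None)
    if name == "model3_adaptation":
        return ModelPreset(name, _PLASTIC_NET, _PLAST_ADAPT, stim, _FULL_RESET, _ADAPT)
    if name == "model3_narrow":
        return ModelPreset(name, _NARROW_NET, _PLAST_DEFAULT, stim, _FULL_RESET, None)
    raise KeyError(
        f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
    )


PRESET_NAMES = (
    "model1",
    "model2",
    "model2_noreset",
    "model2_adaptation",
    "model3",
    "model3_adaptation",
    "model3_narrow",
)


def get_preset(name: str) -> ModelPreset:
    """Return the named parameter preset."""
    return _build(name)


def preset_to_yaml(preset: ModelPreset, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(preset.to_dict(), fh, sort_keys=False)


def preset_from_yaml(path) -> ModelPreset:
    with open(path) as fh:
        return ModelPreset.from_dict(yaml.safe_load(fh))
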