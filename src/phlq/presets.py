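"""Genotype/condition presets: kinetic parameter sets for the transporter
variants and perturbations studied with VGLUT-pHluorin reporters.

Each preset fixes the generative constants of one condition — endocytic and
exocytic time constants, recycling/readily-releasable pool fractions, and
resting surface fraction.  Fields without a condition-specific measurement
inherit the corresponding wild-type hippocampal value.  Pharmacological and
knockdown conditions re-parameterize the kinetics only; no adaptor-protein
mechanism is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import KineticParams

_WT_SURFACE = 0.024  # resting surface fraction of wild-type VGLUT-pH


@dataclass(frozen=True)
class GenotypePreset:
    name: str
    params: KineticParams
    description: str = ""


def _p(**kw) -> KineticParams:
    base = dict(
        total_pool=1000.0,
        surface_frac=_WT_SURFACE,
        rp_frac=0.5173,
        rrp_frac=0.0532,
        tau_endo=25.20,
        tau_exo=27.16,
    )
    base.update(kw)
    return KineticParams(**base)


PRESETS: dict[str, GenotypePreset] = {
    p.name: p
    for p in [
        GenotypePreset(
            "VGLUT2",
            _p(),
            "wild-type VGLUT2-pH in hippocampal neurons",
        ),
        GenotypePreset(
            "VGLUT1",
            _p(tau_endo=14.18, tau_exo=17.71, rp_frac=0.5338, rrp_frac=0.0724),
            "wild-type VGLUT1-pH in hippocampal neurons",
        ),
        GenotypePreset(
            "VGLUT2/1",
            _p(tau_endo=15.58),
            "VGLUT2 body with the VGLUT1 C-terminal tail (chimera)",
        ),
        GenotypePreset(
            "VGLUT1/2",
            _p(tau_endo=20.20, tau_exo=17.71, rp_frac=0.5338, rrp_frac=0.0724),
            "VGLUT1 body with the VGLUT2 C-terminal tail (chimera)",
        ),
        GenotypePreset(
            "FI/AA",
            _p(tau_endo=123.2, surface_frac=0.0961),
            "dileucine-motif FI->AA mutant: endocytosis severely slowed",
        ),
        GenotypePreset(
            "FI/GG",
            _p(tau_endo=5000.0, surface_frac=0.2922, rp_frac=0.05, rrp_frac=0.01),
            "dileucine-motif FI->GG mutant: surface-stranded, barely responsive",
        ),
        GenotypePreset(
            "VGLUT2+BFA",
            _p(tau_endo=35.99, rp_frac=0.3556),
            "VGLUT2-pH with brefeldin A blocking AP-1/AP-3 pathways",
        ),
        GenotypePreset(
            "vector",
            _p(tau_endo=55.50, rp_frac=0.4575),
            "vector-control lentivirus, high-frequency stimulation series",
        ),
        GenotypePreset(
            "AP1_KD",
            _p(tau_endo=49.45, rp_frac=0.2586),
            "AP-1 gamma knockdown: recycling pool reduced, kinetics unchanged",
        ),
        GenotypePreset(
            "AP3_KD",
            _p(tau_endo=20.40, rp_frac=0.4595),
            "AP-3 delta1 knockdown: endocytosis accelerated, pools unchanged",
        ),
        GenotypePreset(
            "VGLUT2-thalamic",
            _p(tau_endo=54.32, rp_frac=0.4993),
            "VGLUT2-pH expressed in thalamic culture",
        ),
        GenotypePreset(
            "VGLUT1-thalamic",
            _p(tau_endo=24.89, tau_exo=17.71, rp_frac=0.4910, rrp_frac=0.0724),
            "VGLUT1-pH expressed in thalamic culture",
        ),
    ]
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def get_preset(name: str) -> GenotypePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
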