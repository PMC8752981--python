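"""Stylized reference catalog and scenario presets for synthetic cohorts.

The bundled catalog is SYNTHETIC: six fixed, stylized profiles that echo the
channel structure of well-known mutational processes (clock-like CpG
deamination, APOBEC C>T and C>G at TpC, mismatch-repair deficiency,
proofreading-polymerase failure, and a broad homologous-recombination-
deficiency-like profile) without copying any published catalog.  Scenario
presets couple one observed feature to the matching process:

- ``apobec``: high expression of a deaminase-like gene drives the TpC C>T process.
- ``mlh1``: LOW expression of a repair gene drives the MMRd-like process; a
  promoter-methylation feature is generated as the anti-coupled transform.
- ``pole``: a binary mutated/wild-type flag drives the proofreading process.
- ``hrd``: a continuous copy-number-derived score drives the broad HRD-like process.
- ``hypoxia``: a continuous transcriptome score drives the APOBEC-like process,
  so hypoxia-derived signatures co-segregate with the APOBEC profiles.
"""

from __future__ import annotations

import numpy as np

from . import channels as ch
from .catalog import SignatureCatalog
from .simulate import AntiFeature, CausalLink, MutationCountSpec, SimulationConfig

#: signature names of the stylized catalog
CLOCK = "Clock-CpG"
APOBEC_CT = "APOBEC-TpC-CtoT"
APOBEC_CG = "APOBEC-TpC-CtoG"
MMRD = "MMRd-like"
POLE = "POLE-like"
HRD = "HRD-like"

_FLOOR = 0.04  # fraction of mass spread uniformly so no channel is exactly zero


def _profile(peaks: dict[int, float]) -> np.ndarray:
    p = np.full(ch.N_CHANNELS, _FLOOR / ch.N_CHANNELS)
    total = sum(peaks.values())
    for idx, w in peaks.items():
        p[idx] += (1.0 - _FLOOR) * w / total
    return p


def _chan(five: str, ref: str, alt: str, three: str) -> int:
    return ch.classify_substitution(ref, alt, five, three)


def reference_catalog() -> SignatureCatalog:
    """The six-signature stylized catalog used by the scenario presets."""
    profiles = {
        CLOCK: _profile({_chan(f, "C", "T", "G"): 1.0 for f in "ACGT"}),
        # TpC deaminase preference with the characteristic 3' ranking
        # (A/T strongest, G weakest)
        APOBEC_CT: _profile({_chan("T", "C", "T", t): w
                             for t, w in zip("ACGT", (0.30, 0.22, 0.08, 0.40))}),
        APOBEC_CG: _profile({_chan("T", "C", "G", t): w
                             for t, w in zip("ACGT", (0.30, 0.22, 0.08, 0.40))}),
        MMRD: _profile({**{_chan("G", "C", "T", t): 2.0 for t in "ACT"},
                        **{_chan("A", "T", "C", t): 1.0 for t in "ACGT"}}),
        POLE: _profile({_chan("T", "C", "A", "T"): 0.55,
                        _chan("T", "T", "G", "T"): 0.35,
                        _chan("T", "C", "T", "G"): 0.10}),
        # broad but structured: mass across the C>A, C>G and T>A blocks with
        # context weights rising within each block, echoing the uneven flank
        # preferences of real broad signatures (a flat profile would be poorly
        # identifiable under multinomial sampling noise)
        HRD: _profile({block * 16 + j: float((16 - j) ** 3)
                       for block in (0, 1, 3)
                       for j in range(16)}),
    }
    mat = np.vstack([profiles[name] for name in profiles])
    return SignatureCatalog.from_matrix(mat, list(profiles), renormalize=True)


#: baseline Dirichlet concentrations: the clock-like process dominates the
#: background; every episodic process (APOBEC, MMRd, proofreading, HRD) is
#: near-absent unless causally driven
#: proportions: clock-like ~73% of background mass; total concentration 8 keeps
#: the background share moderately dispersed (clock share sd ~ 0.15) so that
#: tail-percentile group means are estimable at cohort sizes of a few hundred
_BASELINE_ALPHA = {CLOCK: 5.82, APOBEC_CT: 0.436, APOBEC_CG: 0.436,
                   MMRD: 0.436, POLE: 0.436, HRD: 0.436}

SCENARIOS = ("apobec", "mlh1", "pole", "hrd", "hypoxia")


def scenario_config(
    name: str,
    n_samples: int = 300,
    mutations_per_sample: int = 2000,
    coupling: float = 0.8,
    seed: int = 0,
) -> SimulationConfig:
    """Build the SimulationConfig for one named scenario preset."""
    catalog = reference_catalog()
    alpha = np.array([_BASELINE_ALPHA[n] for n in catalog.names])
    links: list[CausalLink]
    anti: list[AntiFeature] = []
    if name == "apobec":
        links = [CausalLink("APOBEC3A_expr", APOBEC_CT, coupling)]
    elif name == "mlh1":
        links = [CausalLink("MLH1_expr", MMRD, -coupling)]
        anti = [AntiFeature("MLH1_meth", "MLH1_expr", noise_sd=0.2)]
    elif name == "pole":
        links = [CausalLink("POLE_mut", POLE, coupling, binary=True)]
    elif name == "hrd":
        links = [CausalLink("HRD_score", HRD, coupling)]
    elif name == "hypoxia":
        links = [CausalLink("hypoxia_score", APOBEC_CT, coupling)]
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return SimulationConfig(
        n_samples=n_samples,
        catalog=catalog,
        causal_map=links,
        anti_features=anti,
        mutations_per_sample=MutationCountSpec(kind="fixed",
                                               median=mutations_per_sample),
        baseline_alpha=alpha,
        seed=seed,
    )


def scenario_causal_signature(name: str) -> str:
    """Name of the catalog signature a scenario preset drives."""
    return {"apobec": APOBEC_CT, "mlh1": MMRD, "pole": POLE,
            "hrd": HRD, "hypoxia": APOBEC_CT}[name]


def scenario_feature(name: str) -> str:
    """Name of the observed driving feature of a scenario preset."""
    return {"apobec": "APOBEC3A_expr", "mlh1": "MLH1_expr", "pole": "POLE_mut",
            "hrd": "HRD_score", "hypoxia": "hypoxia_score"}[name]
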