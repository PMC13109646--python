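"""Reference cohort parameterization.

Published cohort statistics (mean, SD, n of oocytes; permeabilities on the
1e-6 cm/s scale) for shark aquaglyceroporins and Aqp8 expressed in Xenopus
oocytes, alongside water-injected controls.  Constructs are from the
sharpnose sevengill shark (Hpe), elephant shark (Cmi) and whitespotted
bambooshark (Cpl).  These serve as generating values for the simulated
parameter-recovery surface: cohorts drawn from these distributions and
pushed through the full pipeline should return the same means up to
sampling error.
"""

from __future__ import annotations

from .swell_model import AssayTruth, CohortSpec, ConstructSpec, SimDefaults

__all__ = ["REFERENCE_COHORTS", "reference_construct", "reference_cohort_spec"]

# construct -> assay -> (mean, sd, n) on the 1e-6 cm/s scale
REFERENCE_COHORTS: dict[str, dict[str, tuple[float, float, int]]] = {
    "Control": {
        "water": (1.1, 0.4, 26),
        "glycerol": (1.8, 0.6, 27),
        "urea": (0.1, 0.4, 26),
        "boric_acid": (0.3, 0.3, 23),
    },
    "HpeAqp3c1": {
        "water": (1.2, 0.3, 12),
        "glycerol": (0.3, 0.4, 12),
        "urea": (-0.1, 0.2, 12),
        "boric_acid": (0.3, 0.3, 12),
    },
    "HpeAqp3c2": {
        "water": (8.9, 3.3, 12),
        "glycerol": (8.0, 5.6, 12),
        "urea": (0.9, 0.3, 12),
        "boric_acid": (0.7, 0.3, 12),
    },
    "HpeAqp8": {
        "water": (9.9, 3.8, 12),
        "glycerol": (0.1, 0.2, 10),
        "urea": (0.9, 0.4, 12),
        "boric_acid": (1.6, 0.6, 12),
    },
    "HpeAqp9": {
        "water": (8.6, 3.5, 14),
        "glycerol": (47.1, 21.3, 13),
        "urea": (44.5, 14.4, 14),
        "boric_acid": (54.6, 22.7, 16),
    },
    "HpeAqp10c1": {
        "water": (11.8, 3.7, 9),
        "glycerol": (2.6, 1.0, 12),
        "urea": (0.2, 0.2, 9),
        "boric_acid": (0.5, 0.3, 11),
    },
    "HpeAqp10c2": {
        "water": (4.3, 1.8, 22),
        "glycerol": (17.6, 7.0, 23),
        "urea": (0.7, 0.4, 23),
        "boric_acid": (0.7, 0.4, 22),
    },
    "CmiAqp3c1": {
        "water": (1.4, 0.5, 12),
        "glycerol": (0.1, 0.2, 10),
        "urea": (-0.2, 0.3, 11),
        "boric_acid": (0.1, 0.3, 11),
    },
    "CmiAqp3c2": {
        "water": (10.8, 5.0, 12),
        "glycerol": (21.9, 7.0, 10),
        "urea": (1.5, 0.8, 9),
        "boric_acid": (0.8, 0.4, 12),
    },
    "CplAqp3c1": {
        "water": (1.2, 0.3, 11),
        "glycerol": (-0.1, 0.3, 10),
        "urea": (-0.1, 0.3, 11),
        "boric_acid": (0.0, 0.3, 12),
    },
    "CplAqp3c2": {
        "water": (10.7, 3.0, 12),
        "glycerol": (4.3, 1.9, 12),
        "urea": (0.5, 0.3, 12),
        "boric_acid": (0.5, 0.4, 12),
    },
}


def reference_construct(name: str, assays: list[str] | None = None) -> ConstructSpec:
    """ConstructSpec for a published construct, optionally restricted to assays."""
    table = REFERENCE_COHORTS[name]
    labels = assays if assays is not None else list(table)
    return ConstructSpec(
        construct=name,
        assays={lab: AssayTruth(n=table[lab][2], mean=table[lab][0], sd=table[lab][1]) for lab in labels},
    )


def reference_cohort_spec(
    constructs: list[str] | None = None,
    assays: list[str] | None = None,
    seed: int = 0,
    defaults: SimDefaults | None = None,
) -> CohortSpec:
    """Cohort design mirroring the published experiment (or a subset of it)."""
    names = constructs if constructs is not None else list(REFERENCE_COHORTS)
    return CohortSpec(
        constructs=tuple(reference_construct(n, assays) for n in names),
        defaults=defaults if defaults is not None else SimDefaults(),
        seed=seed,
    )
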