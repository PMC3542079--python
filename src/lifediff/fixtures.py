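"""Named kinetic-model presets.

Two families of models are bundled:

* ``demo_*`` — the didactic one- and two-state models used throughout the
  documentation and the simulation walkthrough (slow stable state, fast
  weakly bound state, optional switching between them).
* ``pten3_*`` / ``pten2_*`` — reference parameter sets for the PTEN
  (G129E phosphatase-dead mutant) membrane-binding kinetics in
  *Dictyostelium*: three- and two-state fits for non-polarized cells, the
  tail (posterior) and pseudopod (anterior) membrane of polarized cells,
  and the N-terminal Δ15 deletion mutant.  These store the *apparent*
  (photobleaching-uncorrected, ``λ_b = 0.1 1/s``) per-state decay rates
  exactly as estimated, with ``lam_b = 0`` so that simulations and
  steady-state calculations reproduce the observable decays.  State 1 of
  the three-state fits dissociates more slowly than the fluorophore
  bleaches, so its true dissociation rate is not determined.

All coordinates are µm, all times s.
"""

from __future__ import annotations

import numpy as np

from .models import KineticModel

__all__ = ["make_fixture", "list_fixtures", "DEFAULT_PHOTOBLEACH_RATE",
           "MU_NONPOLAR", "MU_TAIL", "MU_PSEUDOPOD", "MEM_CYT_RATIO",
           "PTEN3_NONPOLAR_FRACTIONS"]

#: Photobleaching rate constant of the TMR label measured on immobilized
#: molecules in fixed cells, 1/s.
DEFAULT_PHOTOBLEACH_RATE = 0.1

#: Bulk membrane-to-cytosol molecule ratio of PTEN(G129E) in
#: non-polarized cells (biochemical fractionation).
MEM_CYT_RATIO = 0.76

#: Region-resolved association frequencies (1/s) for polarized cells,
#: derived from the ~60% pseudopod/tail total-frequency ratio.
MU_NONPOLAR = (0.54, 1.38, 0.36)
MU_TAIL = (0.68, 1.32, 0.27)
MU_PSEUDOPOD = (0.06, 1.21, 0.16)

#: Time-pooled displacement-mixture fractions of the non-polarized
#: three-state fit (companion to the ``pten3_nonpolar`` rates).
PTEN3_NONPOLAR_FRACTIONS = (0.479, 0.480, 0.041)


def _norm(q):
    q = np.asarray(q, dtype=float)
    return q / q.sum()


def _pten3(name, note, D, lam_apparent, k12, k21, k23, k32, q, eps):
    # chain topology 1-2-3: no direct 1<->3 transitions
    return KineticModel(
        D=D, lam=lam_apparent,
        k={(0, 1): k12, (1, 0): k21, (1, 2): k23, (2, 1): k32},
        q=_norm(q), lam_b=0.0, eps=eps, name=name,
        note=note + " Apparent (bleaching-uncorrected) per-state decay rates.")


def _pten2(name, note, D, lam_apparent, k12, k21, q, eps=0.036):
    return KineticModel(
        D=D, lam=lam_apparent, k={(0, 1): k12, (1, 0): k21},
        q=_norm(q), lam_b=0.0, eps=eps, name=name,
        note=note + " Apparent (bleaching-uncorrected) per-state decay rates.")


_FIXTURES = {
    # -- didactic models ---------------------------------------------------
    "demo_1state": lambda: KineticModel(
        D=[0.01], lam=[1.00], q=[1.0], eps=0.04, name="demo_1state",
        note="Single binding state: D = 0.01 µm²/s, λ = 1.0 1/s."),
    "demo_2state_static": lambda: KineticModel(
        D=[0.01, 0.10], lam=[0.10, 1.00], q=[0.20, 0.80], eps=0.04,
        name="demo_2state_static",
        note="Two binding states without transitions; the state is fixed "
             "at association."),
    "demo_2state_switching": lambda: KineticModel(
        D=[0.01, 0.10], lam=[0.10, 1.00], k={(0, 1): 0.10, (1, 0): 0.50},
        q=[0.20, 0.80], eps=0.04, name="demo_2state_switching",
        note="Two binding states with transitions k12 = 0.10, "
             "k21 = 0.50 1/s; the standard pipeline walkthrough model."),
    # -- PTEN(G129E) three-state fits --------------------------------------
    "pten3_nonpolar": lambda: _pten3(
        "pten3_nonpolar",
        "PTEN G129E, non-polarized cells, three-state fit (1967 molecules).",
        D=[0.035, 0.133, 0.693], lam_apparent=[0.037, 3.995, 12.525],
        k12=6.289, k21=2.896, k23=0.406, k32=0.029,
        q=[0.238, 0.606, 0.157], eps=0.036),
    "pten3_tail": lambda: _pten3(
        "pten3_tail",
        "PTEN G129E, posterior (tail) membrane of polarized cells, "
        "three-state fit (1583 molecules).",
        D=[0.034, 0.150, 0.722], lam_apparent=[0.010, 4.708, 13.919],
        k12=4.663, k21=4.187, k23=0.414, k32=0.028,
        q=[0.298, 0.581, 0.121], eps=0.037),
    "pten3_pseudopod": lambda: _pten3(
        "pten3_pseudopod",
        "PTEN G129E, anterior (pseudopod) membrane of polarized cells, "
        "three-state fit (865 molecules).",
        D=[0.039, 0.115, 0.557], lam_apparent=[0.039, 4.624, 12.947],
        k12=5.433, k21=1.928, k23=0.434, k32=0.043,
        q=[0.041, 0.851, 0.108], eps=0.033),
    "pten3_d15": lambda: _pten3(
        "pten3_d15",
        "PTEN G129E Δ15 (PtdIns(4,5)P2-motif deletion), non-polarized "
        "cells, three-state fit (504 molecules).",
        D=[0.013, 0.161, 0.861], lam_apparent=[0.066, 3.303, 6.675],
        k12=6.382, k21=2.356, k23=0.359, k32=0.024,
        q=[0.180, 0.561, 0.259], eps=0.036),
    # -- PTEN(G129E) two-state fits ----------------------------------------
    "pten2_nonpolar": lambda: _pten2(
        "pten2_nonpolar",
        "PTEN G129E, non-polarized cells, two-state fit.",
        D=[0.067, 0.435], lam_apparent=[1.510, 9.998],
        k12=2.592, k21=8.155, q=[0.646, 0.354]),
    "pten2_tail": lambda: _pten2(
        "pten2_tail",
        "PTEN G129E, posterior (tail) membrane, two-state fit.",
        D=[0.052, 0.389], lam_apparent=[1.160, 9.359],
        k12=1.553, k21=3.653, q=[0.625, 0.375]),
    "pten2_pseudopod": lambda: _pten2(
        "pten2_pseudopod",
        "PTEN G129E, anterior (pseudopod) membrane, two-state fit.",
        D=[0.077, 0.406], lam_apparent=[2.431, 13.142],
        k12=0.688, k21=0.0, q=[0.697, 0.303]),
    "pten2_d15": lambda: _pten2(
        "pten2_d15",
        "PTEN G129E Δ15, non-polarized cells, two-state fit.",
        D=[0.057, 0.551], lam_apparent=[1.131, 6.252],
        k12=0.966, k21=0.0, q=[0.512, 0.488]),
}


def list_fixtures() -> list:
    """Names of all bundled model presets."""
    return sorted(_FIXTURES)


def make_fixture(name: str) -> KineticModel:
    """Return the named kinetic-model preset.

    Raises ``KeyError`` with the list of valid names for typos.
    """
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"available: {', '.join(list_fixtures())}") from None
    return factory()
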