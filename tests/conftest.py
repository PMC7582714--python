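"""Shared fixtures and the independent enumeration oracle.

The oracle expands every binding polynomial into its explicit sum over
occupancy microstates with binomial coefficients, so it shares no code path
with the closed-form implementation it checks.
"""

from __future__ import annotations

from math import comb

import pytest

import allokin as ak
from allokin import fitting, synth


# ---------------------------------------------------------------- oracle --


def oracle_sum(K: float, c: float, sites: int) -> float:
    """Explicit microstate sum equal to (1 + K c)^sites."""
    return sum(comb(sites, i) * (K * c) ** i for i in range(sites + 1))


def oracle_weights(scheme, L: float, form: str) -> tuple[float, float]:
    if form == "unbound":
        w_A = oracle_sum(scheme.K_AU, L, scheme.n)
        w_B = (
            scheme.L_U
            * oracle_sum(scheme.K_BI, L, scheme.m)
            * oracle_sum(scheme.K_BU, L, scheme.n)
        )
    else:
        w_A = oracle_sum(scheme.K_AL, L, scheme.n)
        w_B = scheme.L_L * oracle_sum(scheme.K_BL, L, scheme.n)
    return w_A, w_B


def oracle_kcat(scheme, L: float) -> float:
    w_A, w_B = oracle_weights(scheme, L, "substrate_bound")
    return (scheme.kcat_A * w_A + scheme.kcat_B * w_B) / (w_A + w_B)


def oracle_km(scheme, L: float) -> float:
    u_A, u_B = oracle_weights(scheme, L, "unbound")
    b_A, b_B = oracle_weights(scheme, L, "substrate_bound")
    return scheme.km_0 * (u_A + u_B) / (b_A + b_B)


def oracle_efficiency(scheme, L: float) -> float:
    u_A, u_B = oracle_weights(scheme, L, "unbound")
    eff_A = scheme.kcat_A / scheme.km_A
    eff_B = scheme.kcat_B / scheme.km_B
    return (eff_A * u_A + eff_B * u_B) / (u_A + u_B)


# -------------------------------------------------------------- fixtures --


@pytest.fixture(scope="session")
def h20s():
    return ak.fixture_scheme("H20S_LIKE")


@pytest.fixture(scope="session")
def y20s():
    return ak.fixture_scheme("Y20S_LIKE")


@pytest.fixture(scope="session")
def a3dn():
    return ak.fixture_scheme("A3DN_LIKE")


@pytest.fixture(scope="session")
def all_schemes(h20s, y20s, a3dn):
    return {"H20S_LIKE": h20s, "Y20S_LIKE": y20s, "A3DN_LIKE": a3dn}


@pytest.fixture(scope="session")
def h20s_selection(h20s):
    """Minimal-(n, m) selection on the noiseless human-like profile
    (shared: the full candidate sweep is the most expensive computation)."""
    profile = synth.model_profile(h20s)
    return fitting.select_site_numbers(profile)


@pytest.fixture(scope="session")
def y20s_selection(y20s):
    profile = synth.model_profile(y20s)
    return fitting.select_site_numbers(profile)
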