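"""Shared fixtures: benchmark cases and cached expensive wash runs."""

from __future__ import annotations

from dataclasses import replace

import pytest

import cakewash as cw


@pytest.fixture(scope="session")
def pcm_water_fx():
    return cw.generate_fixture("pcm_water")


@pytest.fixture(scope="session")
def pcm_heptane_fx():
    return cw.generate_fixture("pcm_heptane")


@pytest.fixture(scope="session")
def ma_heptane_fx():
    return cw.generate_fixture("ma_heptane")


def _flash(fx):
    return replace(fx, kinetics=replace(fx.kinetics, mode="instantaneous_flash"))


# cached heavy runs (the 2b/2c equilibrium integrations dominate runtime)


@pytest.fixture(scope="session")
def run_2b_water(pcm_water_fx):
    return cw.run_case(pcm_water_fx, "2b")


@pytest.fixture(scope="session")
def run_2b_heptane(pcm_heptane_fx):
    return cw.run_case(pcm_heptane_fx, "2b")


@pytest.fixture(scope="session")
def run_2c_water(pcm_water_fx):
    return cw.run_case(pcm_water_fx, "2c")


@pytest.fixture(scope="session")
def run_2c_heptane(pcm_heptane_fx):
    return cw.run_case(pcm_heptane_fx, "2c")


@pytest.fixture(scope="session")
def run_2c_water_flash(pcm_water_fx):
    return cw.run_case(_flash(pcm_water_fx), "2c")


@pytest.fixture(scope="session")
def run_2c_heptane_flash(pcm_heptane_fx):
    return cw.run_case(_flash(pcm_heptane_fx), "2c")


@pytest.fixture(scope="session")
def run_2b_water_flash(pcm_water_fx):
    return cw.run_case(_flash(pcm_water_fx), "2b")


@pytest.fixture(scope="session")
def run_2b_heptane_flash(pcm_heptane_fx):
    return cw.run_case(_flash(pcm_heptane_fx), "2b")
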