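import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from timsccs.adducts import (
    ISOTOPES,
    IsotopePattern,
    annotate_peaks,
    pattern_deviation,
    species_mz,
    theoretical_isotope_pattern,
)
from timsccs.core import CompoundRecord, parse_formula
from timsccs.mobilogram import extract_bpm, pick_peaks, smooth
from timsccs.physics import MobilityPhysicsContext
from timsccs.simulate import SimulatedCompound, SimulatedSpecies, SimulationSpec, simulate_frames


def multinomial_pattern_oracle(formula: str, n_bins: int = 4) -> list[float]:
    """Brute-force isotopologue distribution by multinomial enumeration.

    For each element, enumerate every isotope count vector over its atoms
    and weight by the exact multinomial probability; combine elements by
    nested summation over extra-neutron counts.
    """
    counts = parse_formula(formula)
    per_element: list[dict[int, float]] = []
    for element, n in counts.items():
        isotopes = ISOTOPES[element]
        mono = isotopes[0][0]
        offsets = [round(m - mono) for m, _ in isotopes]
        dist: dict[int, float] = {}
        for combo in itertools.product(range(n + 1), repeat=len(isotopes) - 1):
            rest = sum(combo)
            if rest > n:
                continue
            ks = (n - rest,) + combo
            prob = math.factorial(n)
            for k, (_, ab) in zip(ks, isotopes):
                prob = prob * ab**k / math.factorial(k)
            extra = sum(k * o for k, o in zip(ks, offsets))
            dist[extra] = dist.get(extra, 0.0) + prob
        per_element.append(dist)

    total: dict[int, float] = {0: 1.0}
    for dist in per_element:
        new: dict[int, float] = {}
        for o1, p1 in total.items():
            for o2, p2 in dist.items():
                if o1 + o2 < n_bins + 2:
                    new[o1 + o2] = new.get(o1 + o2, 0.0) + p1 * p2
        total = new
    probs = [total.get(o, 0.0) for o in range(n_bins)]
    base = max(probs)
    return [p / base for p in probs]


class TestSpeciesMz:
    def test_rutin_nominal_mz_integers(self, rutin):
        M = rutin.monoisotopic_mass
        assert species_mz(M, "[M-H]-") == pytest.approx(609.14610, abs=2e-5)
        assert round(species_mz(M, "[M-H]-")) == 609
        assert round(species_mz(M, "[M-H+Na+HCO2]-")) == 677
        assert round(species_mz(M, "[M-3H]-")) == 607

    def test_dimer_identity(self):
        """[2M-H]- of M equals [M-H]- of 2M exactly."""
        M = 350.123456
        assert species_mz(M, "[2M-H]-") == pytest.approx(
            species_mz(2 * M, "[M-H]-"), abs=1e-12
        )

    @settings(deadline=None, max_examples=30)
    @given(m=st.floats(150.0, 900.0), scale=st.floats(1.1, 3.0))
    def test_affine_in_neutral_mass(self, m, scale):
        for sp in ("[M-H]-", "[M-3H]-", "[M-H+HCO2H]-", "[M-H+Na+HCO2]-"):
            delta = species_mz(m * scale, sp) - species_mz(m, sp)
            assert delta == pytest.approx(m * (scale - 1.0), rel=1e-12)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            species_mz(300.0, "[M+H]+")


class TestIsotopePattern:
    def test_h2_m1_ratio_closed_form(self):
        p = theoretical_isotope_pattern("H2")
        ratio_d = ISOTOPES["H"][1][1] / ISOTOPES["H"][0][1]
        assert p.intensities[1] / p.intensities[0] == pytest.approx(
            2 * ratio_d, rel=1e-6
        )

    @pytest.mark.parametrize(
        "formula, lo, hi",
        [("C6H12O6", 0.064, 0.070), ("C27H30O16", 0.295, 0.315)],
    )
    def test_m1_ratio_in_expected_band(self, formula, lo, hi):
        p = theoretical_isotope_pattern(formula)
        assert lo <= p.intensities[1] / p.intensities[0] <= hi

    @pytest.mark.parametrize("formula", ["C6H12O6", "C27H30O16", "C10H14N5O7P", "C8H15NO6S"])
    def test_convolution_matches_multinomial_oracle(self, formula):
        p = theoretical_isotope_pattern(formula)
        oracle = multinomial_pattern_oracle(formula)
        for got, expected in zip(p.intensities, oracle):
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_masses_strictly_increasing_by_one(self):
        p = theoretical_isotope_pattern("C27H30O16")
        diffs = np.diff(p.masses)
        assert np.all(diffs > 0.99) and np.all(diffs < 1.01)

    def test_unsupported_element_named(self):
        with pytest.raises(ValueError, match="Zr"):
            theoretical_isotope_pattern({"Zr": 1})


class TestPatternDeviation:
    def test_identical_patterns_zero(self):
        p = theoretical_isotope_pattern("C27H30O16")
        assert pattern_deviation(p, p) == 0.0

    def test_hand_computed_value(self):
        theo = IsotopePattern(masses=(100.0, 101.0), intensities=(1.0, 0.3))
        obs = IsotopePattern(masses=(100.0, 101.0), intensities=(1.0, 0.31))
        expected = 1000 * math.sqrt((0.0**2 + 0.01**2) / 2)
        assert pattern_deviation(obs, theo) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(7.07, abs=0.01)

    def test_symmetric(self):
        a = IsotopePattern(masses=(100.0, 101.0), intensities=(1.0, 0.25))
        b = IsotopePattern(masses=(100.0, 101.0), intensities=(1.0, 0.35))
        assert pattern_deviation(a, b) == pattern_deviation(b, a)


class TestAnnotatePeaks:
    def _rutin_run(self, rutin, ccs_by_species, ctx):
        ions = tuple(
            SimulatedSpecies(sp, ccs, ab) for sp, (ccs, ab) in ccs_by_species.items()
        )
        spec = SimulationSpec(compounds=(SimulatedCompound(rutin, ions),))
        return simulate_frames(spec, ctx)

    def test_three_species_run_fully_annotated(self, rutin, ctx):
        """A rutin-like run with its three prominent ions gets all labels."""
        frames, truth = self._rutin_run(
            rutin,
            {
                "[M-H]-": (231.05, 1.0),
                "[M-3H]-": (218.00, 0.6),
                "[M-H+Na+HCO2]-": (245.50, 0.5),
            },
            ctx,
        )
        peaks = pick_peaks(smooth(extract_bpm(frames)))
        annotated = annotate_peaks(peaks, frames, rutin)
        labels = {ann.species for _, ann in annotated}
        assert {"[M-H]-", "[M-3H]-", "[M-H+Na+HCO2]-"} <= labels

    def test_highest_purity_peak_wins_deprotonated_assignment(self, rutin, ctx):
        # two mobility peaks both containing the [M-H]- m/z; the second
        # peak also carries a co-eluting contaminant that dilutes it
        frames, _ = self._rutin_run(rutin, {"[M-H]-": (231.05, 1.0)}, ctx)
        mz = 609.146108
        contaminated = []
        axis = frames.raw_axis
        from timsccs.physics import inverse_k0_from_ccs

        other_center = (inverse_k0_from_ccs(250.0, mz, ctx))
        for pos, (mzs, intens) in zip(axis, frames.spectra):
            amp = 1.0e4 * np.exp(-0.5 * ((pos - other_center) / 0.012) ** 2)
            if amp > 1e-9:
                mzs = np.append(mzs, [mz, 480.0])
                intens = np.append(intens, [amp, amp * 1.6])
            contaminated.append((mzs, intens))
        from timsccs.mobilogram import FrameStack

        frames2 = FrameStack(raw_axis=axis, spectra=contaminated)
        peaks = pick_peaks(smooth(extract_bpm(frames2)))
        annotated = annotate_peaks(peaks, frames2, rutin, min_purity=0.2)
        mh_peaks = [p for p, a in annotated if a.species == "[M-H]-"]
        assert len(mh_peaks) == 1
        # the clean peak (higher purity) got the label
        clean = [p for p, a in annotated if a.species == "[M-H]-"][0]
        others = [p for p, a in annotated if a.species != "[M-H]-"]
        assert all(clean.purity >= (o.purity or 0.0) for o in others)

    def test_bad_isotope_pattern_rejected_despite_mz_match(self, rutin, ctx):
        frames, _ = self._rutin_run(rutin, {"[M-H]-": (231.05, 1.0)}, ctx)
        # corrupt every M+1 centroid so the pattern no longer matches
        spectra = []
        for mzs, intens in frames.spectra:
            bad = intens.copy()
            bad[(mzs > 609.6) & (mzs < 610.6)] *= 10.0
            spectra.append((mzs, bad))
        from timsccs.mobilogram import FrameStack

        frames2 = FrameStack(raw_axis=frames.raw_axis, spectra=spectra)
        peaks = pick_peaks(smooth(extract_bpm(frames2)))
        annotated = annotate_peaks(peaks, frames2, rutin, pattern_ceiling=50.0)
        assert all(a.species == "unknown" for _, a in annotated)

    def test_no_species_assigned_twice(self, rutin, ctx):
        frames, _ = self._rutin_run(
            rutin, {"[M-H]-": (231.05, 1.0), "[2M-H]-": (330.0, 0.7)}, ctx
        )
        peaks = pick_peaks(smooth(extract_bpm(frames)))
        annotated = annotate_peaks(peaks, frames, rutin)
        assigned = [a.species for _, a in annotated if a.species != "unknown"]
        assert len(assigned) == len(set(assigned))
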