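"""Requirement evaluation and facility profiles: oracles and monotonicity."""

from fractions import Fraction
from itertools import chain, combinations, product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emocready import (
    cascade_profile,
    evaluate_requirement,
    profile_frame,
    signal_readiness,
    sri_index,
)
from emocready.definitions import AlternativeGroup, ResourceRequirement
from emocready.errors import EstimateError
from emocready.inventory_io import FacilityInventory


def _req(*groups):
    return ResourceRequirement(
        groups=tuple(AlternativeGroup(alternatives=tuple(g)) for g in groups)
    )


def _inv(*resources):
    return FacilityInventory("X", "Kenya", "government", False, frozenset(resources))


# -- small strategies over an abstract resource universe --------------------

TOKENS = [f"r{i}" for i in range(12)]

requirements = st.lists(
    st.lists(st.sampled_from(TOKENS), min_size=1, max_size=3, unique=True),
    min_size=0, max_size=4,
).map(lambda gs: _req(*gs))

inventories = st.frozensets(st.sampled_from(TOKENS), max_size=12)


class TestEvaluateRequirement:
    def test_skill_only_requirement_satisfied_by_any_inventory(self):
        assert evaluate_requirement(_inv(), ResourceRequirement())
        assert evaluate_requirement(_inv("anything"), ResourceRequirement())

    def test_missing_conjunct_fails(self):
        req = _req(["ampicillin"], ["gentamicin"], ["metronidazole"])
        assert not evaluate_requirement(_inv("ampicillin", "gentamicin"), req)
        assert evaluate_requirement(
            _inv("ampicillin", "gentamicin", "metronidazole"), req
        )

    def test_proxy_alternative_satisfies_group(self):
        req = _req(["refrigerator", "electricity"])
        assert evaluate_requirement(_inv("electricity"), req)
        assert not evaluate_requirement(_inv("flashlight"), req)

    @settings(derandomize=True, max_examples=60)
    @given(req=requirements)
    def test_agrees_with_brute_force_enumeration(self, req):
        """Exhaustive check against an independent choice-tuple formulation.

        A conjunction of disjunctions holds iff some selection of one
        alternative per group is wholly present; enumerate every inventory
        subset of the requirement's own universe and compare.
        """
        universe = sorted({t for g in req.groups for t in g.alternatives})
        assert len(universe) <= 12
        subsets = chain.from_iterable(
            combinations(universe, k) for k in range(len(universe) + 1)
        )
        for subset in subsets:
            s = frozenset(subset)
            oracle = (
                any(set(choice) <= s for choice in product(*(g.alternatives for g in req.groups)))
                if req.groups else True
            )
            assert evaluate_requirement(s, req) == oracle

    @settings(derandomize=True, max_examples=100)
    @given(req=requirements, inv=inventories, extra=st.sampled_from(TOKENS))
    def test_monotone_under_inventory_growth(self, req, inv, extra):
        """Adding a resource never un-satisfies a requirement."""
        if evaluate_requirement(inv, req):
            assert evaluate_requirement(inv | {extra}, req)


class TestCascadeProfile:
    def test_stage2_items_without_stage1_leave_facility_unready(self, replica_defs):
        casc = replica_defs.cascade("sepsis")
        assert cascade_profile(_inv("sepsis_treat_kit"), casc) == (False, False, False)

    def test_full_inventory_is_ready_through_all_stages(self, replica_defs):
        everything = _inv(*replica_defs.resource_ids)
        for casc in replica_defs.cascades:
            assert cascade_profile(everything, casc) == (True, True, True)

    def test_skill_only_first_stage_holds_with_empty_inventory(self, replica_defs):
        casc = replica_defs.cascade("haemorrhage")
        assert cascade_profile(_inv(), casc) == (True, False, False)

    @settings(derandomize=True, max_examples=100)
    @given(inv=inventories)
    def test_cumulative_monotonicity(self, inv, default_defs):
        """Ready-through-stage-k implies ready-through-stage-(k-1)."""
        resources = sorted(default_defs.resource_ids)
        mapped = frozenset(resources[int(t[1:]) % len(resources)] for t in inv)
        for casc in default_defs.cascades:
            r1, r2, r3 = cascade_profile(mapped, casc)
            assert r1 >= r2 >= r3


class TestSignalFunctions:
    def test_three_drug_antibiotic_tracer(self, default_defs):
        sf = default_defs.signal_function("antibiotic")
        assert signal_readiness(
            _inv("ampicillin", "gentamicin", "metronidazole"), sf
        )
        assert not signal_readiness(_inv("ampicillin", "gentamicin"), sf)

    def test_single_drug_uterotonic_tracer(self, default_defs):
        sf = default_defs.signal_function("uterotonic")
        assert signal_readiness(_inv("oxytocin"), sf)
        assert not signal_readiness(_inv("misoprostol"), sf)

    def test_tracers_subset_of_stage12_groups_in_default_config(self, default_defs):
        """Config-level guarantee: every tracer group is drawn from the linked
        cascade's identify/treat groups, so stage-2 readiness implies
        signal-function readiness."""
        for sf in default_defs.signal_functions:
            casc = default_defs.cascade(sf.linked_emergency_id)
            stage12 = casc.stage(1).group_keys() | casc.stage(2).group_keys()
            assert sf.tracer_requirement.group_keys() <= stage12

    @settings(derandomize=True, max_examples=100)
    @given(inv=inventories)
    def test_stage2_readiness_implies_signal_readiness(self, inv, default_defs):
        resources = sorted(default_defs.resource_ids)
        mapped = frozenset(resources[int(t[1:]) % len(resources)] for t in inv)
        for sf in default_defs.signal_functions:
            casc = default_defs.cascade(sf.linked_emergency_id)
            if cascade_profile(mapped, casc)[1]:
                assert signal_readiness(mapped, sf)


class TestSriIndex:
    def test_bounds_and_exact_ratios(self, default_defs):
        full = _inv(*default_defs.resource_ids)
        assert sri_index(full, default_defs) == 1
        assert sri_index(_inv(), default_defs) == 0
        n_groups = len(default_defs.tracer_group_keys())
        one = sri_index(_inv("oxytocin"), default_defs)
        # the oxytocin group appears in two functions but counts once (distinct groups)
        assert one == Fraction(1, n_groups)

    def test_half_of_groups_satisfied_gives_half(self):
        from emocready.definitions import (
            DefinitionSet, ResourceItem, CascadeDefinition,
            SignalFunctionDefinition,
        )
        resources = tuple(
            ResourceItem(resource_id=r, category="drug") for r in ("a", "b")
        )
        defs = DefinitionSet(
            resources=resources,
            cascades=(
                CascadeDefinition(
                    emergency_id="e",
                    stage_requirements=(
                        ResourceRequirement(), _req(["a"]), _req(["b"])
                    ),
                ),
            ),
            signal_functions=(
                SignalFunctionDefinition(
                    function_id="f", function_type="medical_treatment",
                    linked_emergency_id="e",
                    tracer_requirement=_req(["a"], ["b"]),
                ),
            ),
        )
        assert sri_index(_inv("a"), defs) == Fraction(1, 2)

    def test_no_tracer_groups_is_an_error(self, default_defs):
        bare = default_defs.model_copy(update={"signal_functions": ()})
        with pytest.raises(EstimateError):
            sri_index(_inv(), bare)


def test_profile_frame_is_binary_matrix_with_one_row_per_facility(
    replica_cohort, replica_defs
):
    frame = profile_frame(replica_cohort, replica_defs)
    assert len(frame) == replica_cohort.n
    indicator_cols = [c for c in frame.columns if c not in ("facility_id", "sri_index")]
    assert set(frame[indicator_cols].to_numpy().ravel()) <= {0, 1}
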