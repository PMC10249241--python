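import math

import pytest

from protfun.ontology import (GoDag, IcTable, OboParseError, estimate_ic,
                              load_obo, propagate_annotations, propagate_scores)

from conftest import random_dag
from oracle import brute_ancestors, brute_propagate_scores

MINIMAL_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: A
namespace: biological_process
alt_id: GO:0000099
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: B
namespace: biological_process
is_a: GO:0000002 ! A

[Term]
id: GO:0000004
name: gone
namespace: biological_process
is_a: GO:0000001
is_obsolete: true
"""


class TestLoadObo:
    def test_minimal_chain(self, tmp_path):
        path = tmp_path / "go.obo"
        path.write_text(MINIMAL_OBO)
        dags = load_obo(path)
        assert set(dags) == {"BP"}
        dag = dags["BP"]
        assert dag.root == "GO:0000001"
        assert dag.parents["GO:0000003"] == {"GO:0000002"}
        assert dag.parents["GO:0000002"] == {"GO:0000001"}

    def test_obsolete_term_excluded(self, tmp_path):
        path = tmp_path / "go.obo"
        path.write_text(MINIMAL_OBO)
        assert "GO:0000004" not in load_obo(path)["BP"].terms

    def test_alt_id_resolves(self, tmp_path):
        path = tmp_path / "go.obo"
        path.write_text(MINIMAL_OBO)
        assert load_obo(path)["BP"].resolve("GO:0000099") == "GO:0000002"

    def test_cyclic_is_a_rejected(self, tmp_path):
        cyc = MINIMAL_OBO + "\n[Term]\nid: GO:0000005\nnamespace: biological_process\nis_a: GO:0000006\n\n[Term]\nid: GO:0000006\nnamespace: biological_process\nis_a: GO:0000005\n"
        path = tmp_path / "cyc.obo"
        path.write_text(cyc)
        with pytest.raises((OboParseError, ValueError)):
            load_obo(path)


class TestDagValidation:
    def test_parent_outside_terms_rejected(self):
        with pytest.raises(ValueError, match="outside the DAG"):
            GoDag(terms=frozenset({"r", "a"}),
                  parents={"r": frozenset(), "a": frozenset({"ghost"})},
                  namespace="SYN", root="r")

    def test_orphan_non_root_rejected(self):
        with pytest.raises(ValueError, match="no parents"):
            GoDag(terms=frozenset({"r", "a"}),
                  parents={"r": frozenset(), "a": frozenset()},
                  namespace="SYN", root="r")


class TestAncestors:
    def test_root_closure_is_itself(self, chain_dag):
        assert chain_dag.ancestors("root") == {"root"}

    def test_chain_closure(self, chain_dag):
        assert chain_dag.ancestors("B") == {"B", "A", "root"}

    def test_diamond_closure(self, diamond_dag):
        assert diamond_dag.ancestors("B") == {"B", "A", "C", "root"}

    def test_unknown_term_is_key_error(self, chain_dag):
        with pytest.raises(KeyError):
            chain_dag.ancestors("nope")

    def test_matches_brute_force_on_random_dags(self, rng):
        for _ in range(20):
            dag = random_dag(rng, int(rng.integers(2, 50)))
            for term in dag.terms:
                assert dag.ancestors(term) == brute_ancestors(dag.parents, term)


class TestPropagateAnnotations:
    def test_chain_closure(self, chain_dag):
        assert propagate_annotations(chain_dag, {"p1": {"B"}}) == {
            "p1": {"B", "A", "root"}
        }

    def test_idempotent(self, diamond_dag):
        once = propagate_annotations(diamond_dag, {"p1": {"B", "C"}})
        assert once == {"p1": {"B", "A", "C", "root"}}
        assert propagate_annotations(diamond_dag, once) == once

    def test_unknown_term_lists_offenders(self, chain_dag):
        with pytest.raises(ValueError, match=r"p1.*ghost"):
            propagate_annotations(chain_dag, {"p1": {"ghost"}})


class TestPropagateScores:
    def test_parent_raised_to_child(self, chain_dag):
        out = propagate_scores(chain_dag, {"p": {"B": 0.9, "A": 0.3}})
        assert out["p"]["A"] == 0.9
        assert out["p"]["root"] == 0.9

    def test_monotone_input_unchanged(self, chain_dag):
        preds = {"p": {"B": 0.3, "A": 0.5, "root": 0.9}}
        assert propagate_scores(chain_dag, preds) == preds

    def test_diamond_max_over_descendants(self, diamond_dag):
        out = propagate_scores(diamond_dag, {"p": {"B": 0.7, "A": 0.2, "C": 0.5}})
        assert out["p"] == {"B": 0.7, "A": 0.7, "C": 0.7, "root": 0.7}

    def test_score_out_of_range_rejected(self, chain_dag):
        with pytest.raises(ValueError, match="outside"):
            propagate_scores(chain_dag, {"p": {"B": 1.2}})

    def test_threshold_slices_upward_closed_on_random_dags(self, rng):
        """At any threshold the predicted set must contain every parent."""
        for _ in range(15):
            dag = random_dag(rng, int(rng.integers(3, 30)))
            terms = sorted(dag.terms)
            preds = {"p": {t: float(rng.random()) for t in terms
                           if rng.random() < 0.6}}
            out = propagate_scores(dag, preds)
            assert out == brute_propagate_scores(dag.parents, preds)
            for tau in (0.1, 0.4, 0.8):
                P = {t for t, s in out["p"].items() if s >= tau}
                for t in P:
                    assert dag.parents[t] <= P


class TestEstimateIc:
    def test_certain_term_has_zero_ic(self, chain_dag):
        ann = {f"p{i}": {"root", "A"} for i in range(4)}
        ic = estimate_ic(chain_dag, ann)
        assert ic["A"] == pytest.approx(0.0)
        assert ic["root"] == pytest.approx(0.0)

    def test_hand_arithmetic_quarter(self, chain_dag):
        # B in 25 of the 100 proteins that carry its parent A
        ann = {f"p{i}": ({"root", "A", "B"} if i < 25 else {"root", "A"})
               for i in range(100)}
        ic = estimate_ic(chain_dag, ann)
        assert ic["B"] == pytest.approx(-math.log(0.25), abs=1e-9)

    def test_log_base_two(self, chain_dag):
        ann = {f"p{i}": ({"root", "A", "B"} if i < 25 else {"root", "A"})
               for i in range(100)}
        ic = estimate_ic(chain_dag, ann, log_base=2)
        assert ic["B"] == pytest.approx(2.0, abs=1e-9)

    def test_unpropagated_input_rejected(self, chain_dag):
        with pytest.raises(ValueError, match="not propagated"):
            estimate_ic(chain_dag, {"p1": {"B"}})

    def test_zero_count_smoothing_keeps_ic_finite(self, chain_dag):
        ann = {"p1": {"root", "A"}}  # B never observed
        ic = estimate_ic(chain_dag, ann)
        assert math.isfinite(ic["B"]) and ic["B"] >= 0

    def test_ic_non_negative_everywhere(self, rng):
        dag = random_dag(rng, 15)
        terms = sorted(dag.terms)
        raw = {
            f"p{i}": {terms[int(rng.integers(len(terms)))]} for i in range(30)
        }
        ann = propagate_annotations(dag, raw)
        ic = estimate_ic(dag, ann)
        assert all(v >= 0 for v in ic.ic.values())


class TestIcTable:
    def test_negative_ic_rejected(self):
        with pytest.raises(ValueError):
            IcTable(ic={"A": -0.5})

    def test_missing_term_named_in_error(self):
        table = IcTable(ic={"A": 1.0})
        with pytest.raises(KeyError, match="B"):
            table["B"]
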