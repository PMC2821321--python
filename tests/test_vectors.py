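"""Binary vector algebra and image/well/plate variables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenoplate as pp
from phenoplate.data import ImageKey, ImageRecord, ObjectRef, ObjectTable, RelationTable
from phenoplate.vectors import VectorValue


IMG = ImageKey("p", "A01", 0)


def _five_cell_context():
    """One image with 5 cells: 1 and 3 mitotic, 1/4/5 carry a docked spot."""
    df = pd.DataFrame(
        {"plate": "p", "well": "A01", "site": 0, "object_id": [1, 2, 3, 4, 5],
         "area": [10.0, 11.0, 12.0, 13.0, 14.0]}
    )
    ctx = pp.EvalContext()
    ctx.tables["cells"] = ObjectTable(df, "cells")
    ctx.predictions["cells"] = {
        ObjectRef("p", "A01", 0, i): ("mitotic" if i in (1, 3) else "normal")
        for i in range(1, 6)
    }
    rel = RelationTable("cells", "spots", pairs=[(1, 1), (4, 2), (5, 3)],
                        child_counts={1: 1, 2: 0, 3: 0, 4: 1, 5: 1})
    ctx.relations[("cells", "spots")] = {IMG: rel}
    ctx.vectors.add(pp.ClassEquals("mitotic", "cells", class_name="mitotic"))
    ctx.vectors.add(pp.ChildCountCmp("infected", "cells", child_type="spots",
                                     op=">=", threshold=1))
    ctx.vectors.add(pp.Logic("infected_mitotic", "cells", op="AND",
                             operands=("mitotic", "infected")))
    ctx.vectors.add(pp.Logic("not_mitotic", "cells", op="NOT", operands=("mitotic",)))
    ctx.vectors.add(pp.Logic("infected_non_mitotic", "cells", op="AND",
                             operands=("not_mitotic", "infected")))
    return ctx


class TestWorkedExample:
    """The 5-cell scenario: mitotic 1,0,1,0,0; infected 1,0,0,1,1;
    infected mitotic 1,0,0,0,0; infected non-mitotic 0,0,0,1,1."""

    def test_mitotic_vector(self):
        ctx = _five_cell_context()
        v = pp.eval_vector("mitotic", IMG, ctx)
        assert v.flags.tolist() == [1, 0, 1, 0, 0]

    def test_infected_vector(self):
        ctx = _five_cell_context()
        v = pp.eval_vector("infected", IMG, ctx)
        assert v.flags.tolist() == [1, 0, 0, 1, 1]

    def test_infected_mitotic(self):
        ctx = _five_cell_context()
        v = pp.eval_vector("infected_mitotic", IMG, ctx)
        assert v.flags.tolist() == [1, 0, 0, 0, 0]

    def test_infected_non_mitotic(self):
        ctx = _five_cell_context()
        v = pp.eval_vector("infected_non_mitotic", IMG, ctx)
        assert v.flags.tolist() == [0, 0, 0, 1, 1]

    def test_human_label_overrides_prediction(self):
        ctx = _five_cell_context()
        ctx.session_labels["cells"] = {ObjectRef("p", "A01", 0, 2): "mitotic"}
        v = pp.eval_vector("mitotic", IMG, ctx)
        assert v.flags.tolist() == [1, 1, 1, 0, 0]


class TestVectorLogic:
    def _vec(self, flags):
        return VectorValue(IMG, "cells", np.arange(1, len(flags) + 1), np.array(flags))

    def test_and_or_not(self):
        a, b = self._vec([1, 0, 1, 0, 0]), self._vec([1, 0, 0, 1, 1])
        assert pp.vector_logic("AND", a, b).flags.tolist() == [1, 0, 0, 0, 0]
        assert pp.vector_logic("OR", a, b).flags.tolist() == [1, 0, 1, 1, 1]
        assert pp.vector_logic("NOT", a).flags.tolist() == [0, 1, 0, 1, 1]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pp.vector_logic("AND", self._vec([1, 0]), self._vec([1, 0, 1]))

    def test_parent_type_mismatch(self):
        a = self._vec([1, 0])
        b = VectorValue(IMG, "nuclei", np.array([1, 2]), np.array([1, 1]))
        with pytest.raises(ValueError):
            pp.vector_logic("AND", a, b)

    @settings(deadline=None, max_examples=250, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1,
                    max_size=30))
    def test_algebra_laws(self, pairs):
        a = self._vec([p[0] for p in pairs])
        b = self._vec([p[1] for p in pairs])
        AND, OR, NOT = pp.vector_logic, pp.vector_logic, pp.vector_logic
        # De Morgan
        assert NOT("NOT", AND("AND", a, b)).flags.tolist() == \
            OR("OR", NOT("NOT", a), NOT("NOT", b)).flags.tolist()
        # commutativity
        assert AND("AND", a, b).flags.tolist() == AND("AND", b, a).flags.tolist()
        assert OR("OR", a, b).flags.tolist() == OR("OR", b, a).flags.tolist()
        # double negation
        assert NOT("NOT", NOT("NOT", a)).flags.tolist() == a.flags.tolist()

    def test_associativity_three_way(self, rng):
        vs = [self._vec(rng.integers(0, 2, 12).tolist()) for _ in range(3)]
        left = pp.vector_logic("AND", pp.vector_logic("AND", vs[0], vs[1]), vs[2])
        right = pp.vector_logic("AND", vs[0], pp.vector_logic("AND", vs[1], vs[2]))
        assert left.flags.tolist() == right.flags.tolist()


class TestVectorSources:
    def test_attribute_cmp(self):
        ctx = _five_cell_context()
        ctx.vectors.add(pp.AttributeCmp("big", "cells", feature="area", op=">",
                                        threshold=12.0))
        v = pp.eval_vector("big", IMG, ctx)
        assert v.flags.tolist() == [0, 0, 0, 1, 1]

    def test_child_count_oracle(self, rng):
        ctx = _five_cell_context()
        rel = ctx.relations[("cells", "spots")][IMG]
        v = pp.eval_vector("infected", IMG, ctx)
        for oid, flag in zip(v.ids, v.flags):
            assert flag == int(rel.count(int(oid)) >= 1)

    def test_neighbor_in(self):
        ctx = _five_cell_context()
        g = pp.NeighborGraph("cells", {(1, 2), (2, 3), (4, 5)})
        ctx.neighbor_graphs[("cells", IMG)] = g
        ctx.vectors.add(pp.NeighborIn("mitotic_neighbor", "cells", operand="mitotic"))
        v = pp.eval_vector("mitotic_neighbor", IMG, ctx)
        # mitotic = {1,3}; their neighbors: 2 (of both), and nobody else
        assert v.flags.tolist() == [0, 1, 0, 0, 0]

    def test_registry_rejects_bad_defs(self):
        ctx = _five_cell_context()
        with pytest.raises(ValueError, match="undefined"):
            ctx.vectors.add(pp.Logic("x", "cells", op="AND", operands=("nope",)))
        ctx.vectors.add(pp.ClassEquals("nuc_m", "nuclei", class_name="mitotic"))
        with pytest.raises(ValueError, match="parent types"):
            ctx.vectors.add(pp.Logic("y", "cells", op="AND", operands=("nuc_m",)))
        with pytest.raises(ValueError, match="already defined"):
            ctx.vectors.add(pp.ClassEquals("mitotic", "cells", class_name="z"))


class TestImageVariables:
    def test_count(self):
        ctx = _five_cell_context()
        d = pp.ImageVarDef("n_infected_mitotic", "infected_mitotic", "count")
        assert pp.eval_image_var(d, IMG, ctx) == 1.0

    def test_percent(self):
        ctx = _five_cell_context()
        ctx.vectors.add(pp.Logic("all_cells", "cells", op="OR",
                                 operands=("mitotic", "not_mitotic")))
        d = pp.ImageVarDef("pct", "infected_mitotic", "percent_of",
                           reference="all_cells")
        assert pp.eval_image_var(d, IMG, ctx) == pytest.approx(20.0)

    def test_empty_image_missing_percent(self):
        ctx = _five_cell_context()
        empty = ImageKey("p", "A02", 0)
        ctx.tables["cells"] = ObjectTable(
            pd.DataFrame(columns=["plate", "well", "site", "object_id", "area"]),
            "cells",
        )
        d_count = pp.ImageVarDef("n", "mitotic", "count")
        assert pp.eval_image_var(d_count, empty, ctx) == 0.0
        d_pct = pp.ImageVarDef("pct", "mitotic", "percent_of", reference="mitotic")
        assert math.isnan(pp.eval_image_var(d_pct, empty, ctx))


def _well_context(counts_by_image, excluded=()):
    """Wells with one 'count' image measurement per image."""
    ctx = pp.EvalContext()
    meas = {}
    for (well, site), value in counts_by_image.items():
        key = ImageKey("p", well, site)
        ctx.images.append(
            ImageRecord(key, channel_paths={"dna": "x.tif"},
                        excluded=(well, site) in excluded)
        )
        meas[key] = value
    ctx.image_measurements["count"] = meas
    return ctx


class TestWellAndPlateVariables:
    def test_sum_over_images(self):
        ctx = _well_context({("A01", s): v for s, v in enumerate([1, 2, 3, 4])})
        iv = {"count": pp.ImageVarDef("count", "count", "value")}
        d = pp.WellVarDef("total", image_var="count", image_summarizer="sum")
        assert pp.eval_well_var(d, "p", "A01", ctx, iv) == 10.0

    def test_ratio_calculation(self):
        ctx = _well_context({("A01", 0): 5.0})
        ctx.image_measurements["nuclei"] = {ImageKey("p", "A01", 0): 50.0}
        iv = {
            "docked": pp.ImageVarDef("docked", "count", "value"),
            "nuclei": pp.ImageVarDef("nuclei", "nuclei", "value"),
        }
        defs = [
            pp.WellVarDef("docked", image_var="docked"),
            pp.WellVarDef("nuclei", image_var="nuclei"),
            pp.WellVarDef("ratio", calculation=("/", "docked", "nuclei")),
        ]
        out = pp.eval_well_series(defs, [("p", "A01")], ctx, iv)
        assert out["ratio"][("p", "A01")] == pytest.approx(0.1)

    def test_exclusion_bookkeeping(self):
        vals = {("A01", s): v for s, v in enumerate([1, 2, 3, 4])}
        iv = {"count": pp.ImageVarDef("count", "count", "value")}
        d = pp.WellVarDef("total", image_var="count", image_summarizer="sum")
        full = pp.eval_well_var(d, "p", "A01", _well_context(vals), iv)
        drop = pp.eval_well_var(
            d, "p", "A01", _well_context(vals, excluded={("A01", 2)}), iv
        )
        assert full - drop == 3.0  # exactly the excluded image's value

    def test_all_excluded_missing(self):
        ctx = _well_context({("A01", 0): 1.0}, excluded={("A01", 0)})
        iv = {"count": pp.ImageVarDef("count", "count", "value")}
        d = pp.WellVarDef("total", image_var="count")
        assert math.isnan(pp.eval_well_var(d, "p", "A01", ctx, iv))

    def test_plate_singleton(self):
        ctx = _well_context({("A01", 0): 4.0})
        iv = {"count": pp.ImageVarDef("count", "count", "value")}
        wd = pp.WellVarDef("total", image_var="count")
        pv = pp.PlateVarDef("std", "total", wells=("A01",), summarizer="mean")
        out = pp.eval_plate_var(pv, ctx, image_vars=iv, well_defs={"total": wd})
        assert out == 4.0

    def test_log2_self_normalization_zero(self):
        # uniform plate: log2(well / standard) vanishes everywhere
        wells = [f"G{c:02d}" for c in range(1, 13)] + ["A01", "B01"]
        vals = {(w, 0): 8.0 for w in wells}
        ctx = _well_context(vals)
        iv = {"count": pp.ImageVarDef("count", "count", "value")}
        defs = [
            pp.WellVarDef("infected", image_var="count"),
            pp.WellVarDef("norm", calculation=("log2", ("/", "infected", "standard"))),
        ]
        pv = pp.PlateVarDef("standard", "infected",
                            wells=tuple(f"G{c:02d}" for c in range(1, 13)))
        out = pp.eval_well_series(defs, [("p", w) for w in wells], ctx, iv,
                                  plate_vars=[pv])
        for v in out["norm"].values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_empty_well_selection_error(self):
        ctx = _well_context({("A01", 0): 1.0})
        with pytest.raises(ValueError):
            pp.eval_plate_var(pp.PlateVarDef("s", "t", wells=()), ctx)

    def test_missing_propagates_not_zero(self):
        from phenoplate.vectors import _eval_calc

        values = {"a": float("nan"), "b": 2.0}
        assert math.isnan(_eval_calc(("/", "a", "b"), values))
        assert math.isnan(_eval_calc(("/", "b", ("-", "b", "b")), values))  # /0
        assert math.isnan(_eval_calc(("log2", 0.0), values))
        assert _eval_calc(("*", "b", 3.0), values) == 6.0


class TestPopulationDecomposition:
    def test_six_populations_partition_total(self, small_plate, nuclei_table):
        """Crossing mitotic / mitotic-neighbor / normal with the infection
        dichotomy yields 6 populations whose counts sum to the object total
        on every image (mitotic takes precedence over neighbor status)."""
        ctx = small_plate.build_context(nuclei_table)
        truth = small_plate.truth_labels()
        ctx.predictions["nuclei"] = truth  # exact labels: decomposition test
        reg = ctx.vectors
        reg.add(pp.ClassEquals("mitotic", "nuclei", class_name="mitotic"))
        reg.add(pp.NeighborIn("near_mitotic", "nuclei", operand="mitotic"))
        reg.add(pp.Logic("not_mitotic", "nuclei", op="NOT", operands=("mitotic",)))
        reg.add(pp.Logic("neighbor", "nuclei", op="AND",
                         operands=("near_mitotic", "not_mitotic")))
        reg.add(pp.Logic("not_neighbor", "nuclei", op="NOT", operands=("neighbor",)))
        reg.add(pp.Logic("normal", "nuclei", op="AND",
                         operands=("not_mitotic", "not_neighbor")))
        reg.add(pp.ChildCountCmp("infected", "nuclei", child_type="spots",
                                 op=">=", threshold=1))
        reg.add(pp.Logic("not_infected", "nuclei", op="NOT", operands=("infected",)))
        states = ("mitotic", "neighbor", "normal")
        for inf in ("infected", "not_infected"):
            for s in states:
                reg.add(pp.Logic(f"{s}_{inf}", "nuclei", op="AND",
                                 operands=(s, inf)))
        for im in small_plate.images:
            total = len(ctx.object_ids("nuclei", im.key))
            # the 3 states partition the population
            state_counts = [pp.eval_vector(s, im.key, ctx).count for s in states]
            assert sum(state_counts) == total
            # crossing with infection gives 6 populations, still a partition
            six = [
                pp.eval_vector(f"{s}_{inf}", im.key, ctx).count
                for s in states
                for inf in ("infected", "not_infected")
            ]
            assert sum(six) == total

    def test_percent_bounds(self, small_plate, nuclei_table):
        ctx = small_plate.build_context(nuclei_table)
        ctx.predictions["nuclei"] = small_plate.truth_labels()
        ctx.vectors.add(pp.ClassEquals("mitotic", "nuclei", class_name="mitotic"))
        ctx.vectors.add(pp.Logic("not_mitotic", "nuclei", op="NOT",
                                 operands=("mitotic",)))
        ctx.vectors.add(pp.Logic("everyone", "nuclei", op="OR",
                                 operands=("mitotic", "not_mitotic")))
        d = pp.ImageVarDef("pct", "mitotic", "percent_of", reference="everyone")
        for im in small_plate.images:
            v = pp.eval_image_var(d, im.key, ctx)
            assert 0.0 <= v <= 100.0
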