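"""Training modes: random draws, correction passes, boundary/panel candidates,
session merging and blinded presentation."""

import numpy as np
import pandas as pd
import pytest

import phenoplate as pp
from phenoplate.data import ImageKey, ObjectRef, ObjectTable
from phenoplate.training import Candidate


def _table(n_images=10, per_image=5, n_features=3, seed=0, plate="p"):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_images):
        well = f"A{i + 1:02d}"
        for o in range(1, per_image + 1):
            row = {"plate": plate, "well": well, "site": 0, "object_id": o}
            for f in range(n_features):
                row[f"f{f}"] = rng.normal()
            rows.append(row)
    return ObjectTable(pd.DataFrame(rows), "nuclei")


def _two_class_table(seed=0, n_images=10, per_image=10):
    """Objects whose f-features form two overlapping Gaussian classes."""
    rng = np.random.default_rng(seed)
    rows, truth = [], {}
    for i in range(n_images):
        well = f"A{i + 1:02d}"
        for o in range(1, per_image + 1):
            cls = "pos" if rng.random() < 0.5 else "neg"
            mu = 1.0 if cls == "pos" else -1.0
            ref = ObjectRef("p", well, 0, o)
            truth[ref] = cls
            rows.append(
                {"plate": "p", "well": well, "site": 0, "object_id": o,
                 "f0": rng.normal(mu, 1.0), "f1": rng.normal(mu, 1.0)}
            )
    return ObjectTable(pd.DataFrame(rows), "nuclei"), truth


class TestPickRandom:
    def test_forced_single(self):
        t = _table(n_images=1, per_image=1)
        cs = pp.pick_random(t, n=1, seed=0)
        assert cs.refs() == [ObjectRef("p", "A01", 0, 1)]

    def test_deterministic(self):
        t = _table()
        a = pp.pick_random(t, n=5, seed=9).refs()
        b = pp.pick_random(t, n=5, seed=9).refs()
        assert a == b
        assert pp.pick_random(t, n=5, seed=10).refs() != a

    def test_no_eligible_error(self):
        t = _table(n_images=2, per_image=2)
        excl = {ImageKey("p", "A01", 0), ImageKey("p", "A02", 0)}
        with pytest.raises(ValueError):
            pp.pick_random(t, n=1, excluded_images=excl)

    def test_excluded_images_never_sampled(self):
        t = _table(n_images=3, per_image=4)
        excl = {ImageKey("p", "A02", 0)}
        for seed in range(30):
            for r in pp.pick_random(t, n=5, seed=seed, excluded_images=excl).refs():
                assert r.image not in excl

    def test_image_uniformity(self):
        # two images with equal object counts: each should receive ~half of
        # 10,000 single draws (within 3 s.e. of the binomial)
        t = _table(n_images=2, per_image=8)
        hits = sum(
            pp.pick_random(t, n=1, seed=s).refs()[0].well == "A01"
            for s in range(10_000)
        )
        se = np.sqrt(10_000 * 0.25)
        assert abs(hits - 5_000) < 3 * se


class TestCorrectionPass:
    @pytest.fixture()
    def trained(self):
        table, truth = _two_class_table(seed=3)
        X = table.feature_matrix()
        y = np.array([truth[r] for r in table.refs()])
        model = pp.train_model(X, y, C=5, gamma=0.5,
                               feature_names=table.feature_names)
        return table, truth, model

    def test_all_confirmed_stores_nothing(self, trained):
        table, _, model = trained
        img = ImageKey("p", "A01", 0)
        sub = table.subset([r for r in table.refs() if r.image == img])
        preds = dict(zip(sub.refs(), pp.predict(
            model, sub.feature_matrix(model.feature_names), model.feature_names)))
        session = pp.TrainingSession()
        stored = pp.correction_pass(model, table, img, preds, session)
        assert stored == {} and len(session) == 0

    def test_single_disagreement_stored(self, trained):
        table, _, model = trained
        img = ImageKey("p", "A01", 0)
        sub = table.subset([r for r in table.refs() if r.image == img])
        preds = dict(zip(sub.refs(), pp.predict(
            model, sub.feature_matrix(model.feature_names), model.feature_names)))
        ref0 = next(iter(preds))
        user = dict(preds)
        user[ref0] = "pos" if preds[ref0] == "neg" else "neg"
        session = pp.TrainingSession()
        stored = pp.correction_pass(model, table, img, user, session)
        assert stored == {ref0: user[ref0]}
        assert session.labels == stored
        assert session.mode_log[0][1] == "correction"

    def test_set_difference_oracle(self, trained, rng):
        table, _, model = trained
        img = ImageKey("p", "A03", 0)
        sub = table.subset([r for r in table.refs() if r.image == img])
        preds = dict(zip(sub.refs(), pp.predict(
            model, sub.feature_matrix(model.feature_names), model.feature_names)))
        user = {
            r: ("pos" if rng.random() < 0.5 else "neg") for r in preds
        }
        session = pp.TrainingSession()
        stored = pp.correction_pass(model, table, img, user, session)
        expected = {r: c for r, c in user.items() if c != preds[r]}
        assert stored == expected

    def test_unknown_object_rejected(self, trained):
        table, _, model = trained
        img = ImageKey("p", "A01", 0)
        with pytest.raises(KeyError):
            pp.correction_pass(
                model, table, img, {ObjectRef("p", "A01", 0, 999): "pos"},
                pp.TrainingSession(),
            )


class TestBoundaryCandidates:
    @pytest.fixture()
    def trained(self):
        table, truth = _two_class_table(seed=5)
        X = table.feature_matrix()
        y = np.array([truth[r] for r in table.refs()])
        model = pp.train_model(X, y, C=5, gamma=0.5,
                               feature_names=table.feature_names)
        return table, model

    def test_saturation_returns_whole_pool_sorted(self, trained):
        table, model = trained
        cs = pp.boundary_candidates(model, table, n=10_000)
        assert len(cs) == len(table)
        scores = pp.boundary_score(
            model, table.subset(cs.refs()).feature_matrix(model.feature_names),
            model.feature_names,
        )

    def test_sorting_oracle(self, trained):
        table, model = trained
        n = 7
        cs = pp.boundary_candidates(model, table, n=n)
        scores = pp.boundary_score(model, table.feature_matrix(model.feature_names),
                                   model.feature_names)
        expected = [r for _, r in sorted(zip(scores, table.refs()),
                                         key=lambda t: (t[0], t[1]))][:n]
        assert cs.refs() == expected

    def test_labeled_never_returned(self, trained):
        table, model = trained
        labeled = set(table.refs()[:30])
        cs = pp.boundary_candidates(model, table, n=50, labeled=labeled)
        assert not (set(cs.refs()) & labeled)

    def test_empty_pool(self, trained):
        table, model = trained
        cs = pp.boundary_candidates(model, table, n=5, labeled=set(table.refs()))
        assert len(cs) == 0


class TestPanelCandidates:
    @pytest.fixture()
    def trained(self):
        table, truth = _two_class_table(seed=7, n_images=12, per_image=8)
        X = table.feature_matrix()
        y = np.array([truth[r] for r in table.refs()])
        model = pp.train_model(X, y, C=5, gamma=0.5,
                               feature_names=table.feature_names)
        return table, model

    def test_ten_objects_ten_images(self, trained):
        table, model = trained
        cs = pp.panel_candidates(model, table, seed=0)
        assert len(cs) == 10
        assert len({r.image for r in cs.refs()}) == 10
        tags = [c.rationale for c in cs]
        assert tags.count("boundary") == 8
        assert tags.count("exemplar_positive") == 1
        assert tags.count("exemplar_negative") == 1

    def test_exemplars_are_signed_extremes(self, trained):
        table, model = trained
        cs = pp.panel_candidates(model, table, seed=0)
        signed = pp.decision_values(model, table.feature_matrix(model.feature_names),
                                    model.feature_names).iloc[:, 0].to_numpy()
        refs = table.refs()
        pos = next(c.ref for c in cs if c.rationale == "exemplar_positive")
        neg = next(c.ref for c in cs if c.rationale == "exemplar_negative")
        assert pos == refs[int(np.argmax(signed))]
        assert neg == refs[int(np.argmin(signed))]

    def test_saturation(self, trained):
        table, model = trained
        keep = table.refs()[:3]
        labeled = set(table.refs()) - set(keep)
        cs = pp.panel_candidates(model, table, labeled=labeled)
        assert len(cs) == 3

    def test_needs_two_class_model(self, trained):
        table, _ = trained
        X, y = pp.generate_feature_blobs(20, k=3, separation=6, n_features=3, seed=0)
        m3 = pp.train_model(X, y)
        with pytest.raises(ValueError):
            pp.panel_candidates(m3, table)


class TestMergeSessions:
    def _session(self, items):
        s = pp.TrainingSession()
        for ref, cls in items:
            s.label(ref, cls)
        return s

    def test_single_session_all_train(self):
        r = ObjectRef("p", "A01", 0, 1)
        train, val = pp.merge_sessions(self._session([(r, "a")]))
        assert train == {r: "a"} and val == {}

    def test_disjoint_split_sizes_add(self):
        s1 = self._session([(ObjectRef("p", "A01", 0, i), "a") for i in range(1, 5)])
        s2 = self._session([(ObjectRef("p", "A02", 0, i), "b") for i in range(1, 4)])
        train, val = pp.merge_sessions(s1, [s2], split=["train", "validate"])
        assert len(train) == 4 and len(val) == 3

    def test_conflicting_labels_error(self):
        r = ObjectRef("p", "A01", 0, 1)
        s1 = self._session([(r, "a")])
        s2 = self._session([(r, "b")])
        with pytest.raises(ValueError, match="conflict"):
            pp.merge_sessions(s1, [s2], split=["train", "train"])

    def test_object_in_both_roles_error(self):
        r = ObjectRef("p", "A01", 0, 1)
        s1 = self._session([(r, "a")])
        s2 = self._session([(r, "a")])
        with pytest.raises(ValueError, match="both train and validation"):
            pp.merge_sessions(s1, [s2], split=["train", "validate"])

    def test_too_many_sessions(self):
        s = self._session([(ObjectRef("p", "A01", 0, 1), "a")])
        with pytest.raises(ValueError):
            pp.merge_sessions(s, [s] * 11)

    def test_pipeline_matches_manual_holdout(self):
        table, truth = _two_class_table(seed=13)
        refs = table.refs()
        train_refs, val_refs = refs[:60], refs[60:]
        s_train = self._session([(r, truth[r]) for r in train_refs])
        s_val = self._session([(r, truth[r]) for r in val_refs])
        train, val = pp.merge_sessions(s_train, [s_val], split=["train", "validate"])
        Xtr = table.subset(train).feature_matrix()
        ytr = np.array([train[r] for r in table.subset(train).refs()])
        m = pp.train_model(Xtr, ytr, C=5, gamma=0.5,
                           feature_names=table.feature_names)
        sub_val = table.subset(val)
        acc_merge = (pp.predict(m, sub_val.feature_matrix(model_feature_order := m.feature_names), model_feature_order)
                     == np.array([val[r] for r in sub_val.refs()])).mean()
        # manual hold-out with the same partition
        Xv = table.subset(val_refs).feature_matrix()
        yv = np.array([truth[r] for r in table.subset(val_refs).refs()])
        acc_manual = (pp.predict(m, Xv, table.feature_names) == yv).mean()
        assert acc_merge == acc_manual


class TestSessionAndPresent:
    def test_relabel_overwrites_keeps_log(self):
        s = pp.TrainingSession()
        r = ObjectRef("p", "A01", 0, 1)
        s.label(r, "a", mode="default")
        s.label(r, "b", mode="random")
        assert s.labels == {r: "b"}
        assert len(s.mode_log) == 2

    def test_session_roundtrip(self, tmp_path):
        s = pp.TrainingSession()
        s.label(ObjectRef("p", "A01", 0, 1), "a", mode="random")
        s.label(ObjectRef("p", "B02", 1, 3), "b", mode="correction")
        s.save(tmp_path / "s.csv")
        back = pp.TrainingSession.load(tmp_path / "s.csv")
        assert back.labels == s.labels

    def test_present_blinded_hides_filename(self):
        c = Candidate(ObjectRef("p", "A01", 0, 1), "random")
        rec = pp.present(c, filename="img.tif", blinded=True)
        assert "filename" not in rec and rec["blinded"] is True

    def test_present_informed_shows_filename(self):
        c = Candidate(ObjectRef("p", "A01", 0, 1), "random")
        rec = pp.present(c, filename="img.tif", blinded=False)
        assert rec["filename"] == "img.tif"

    def test_blinded_flag_recorded(self):
        s = pp.TrainingSession()
        c = Candidate(ObjectRef("p", "A01", 0, 1), "random")
        pp.present(c, filename="x.tif", blinded=True, session=s)
        assert s.blinded is True
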