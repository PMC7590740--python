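import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

import flowot as fo
from flowot.gating import _restrict_eigenvalues
from flowot.model import DimensionMismatchError
from flowot.templates import Template


def g(mean, cov, weight, label=None):
    return fo.GaussianComponent(mean=mean, cov=cov, weight=weight, label=label)


def three_gaussians_with_outliers(n=3000, outlier_frac=0.05, seed=42):
    rng = np.random.default_rng(seed)
    means = np.array([[0.0, 0.0], [12.0, 0.0], [0.0, 12.0]])
    covs = [np.eye(2), np.diag([2.0, 0.5]), np.array([[1.0, 0.4], [0.4, 1.0]])]
    n_out = int(round(n * outlier_frac))
    n_sig = n - n_out
    counts = rng.multinomial(n_sig, [0.5, 0.3, 0.2])
    X, truth = [], []
    for j, (m, S, c) in enumerate(zip(means, covs, counts)):
        X.append(rng.multivariate_normal(m, S, size=c))
        truth += [j + 1] * c
    X.append(rng.uniform(-10, 25, size=(n_out, 2)))
    truth += [0] * n_out
    X = np.vstack(X)
    perm = rng.permutation(n)
    return X[perm], np.asarray(truth)[perm], means, covs, counts


def init_at(means, covs, weights):
    return fo.TclustInit(
        weights=np.asarray(weights, float),
        means=np.asarray(means, float),
        covs=np.stack([np.asarray(c, float) for c in covs]),
    )


class TestEigenvalueRestriction:
    def test_untouched_when_ratio_ok(self):
        eigs = np.array([[1.0, 2.0], [1.5, 3.0]])
        out = _restrict_eigenvalues(eigs, np.array([10.0, 10.0]), c=10.0)
        np.testing.assert_array_equal(out, eigs)

    def test_ratio_enforced(self):
        eigs = np.array([[0.001, 1.0], [50.0, 100.0]])
        out = _restrict_eigenvalues(eigs, np.array([10.0, 10.0]), c=10.0)
        assert out.max() / out.min() <= 10.0 + 1e-9

    def test_zero_eigenvalues_lifted(self):
        eigs = np.array([[0.0, 1.0]])
        out = _restrict_eigenvalues(eigs, np.array([5.0]), c=4.0)
        assert out.min() > 0
        assert out.max() / out.min() <= 4.0 + 1e-9

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_truncation_is_optimal_over_grid(self, seed):
        """The candidate-set optimum beats a fine grid of truncation levels."""
        rng = np.random.default_rng(seed)
        eigs = rng.uniform(0.01, 10.0, size=(3, 2))
        sizes = rng.uniform(1, 20, size=3)
        c = 3.0
        out = _restrict_eigenvalues(eigs, sizes, c)

        def obj(t):
            tr = np.clip(eigs, t, c * t)
            return (sizes[:, None] * (np.log(tr) + eigs / tr)).sum()

        got = (sizes[:, None] * (np.log(out) + eigs / out)).sum()
        grid = np.geomspace(eigs.min() / c, eigs.max(), 400)
        assert got <= min(obj(t) for t in grid) + 1e-6


class TestTclustFit:
    def test_trimmed_set_size_exact(self):
        X, _, means, covs, _ = three_gaussians_with_outliers(n=100)
        params = fo.TclustParams(k=3, alpha=0.05)
        res = fo.tclust_fit(X, params, init_at(means, covs, [0.5, 0.3, 0.2]))
        assert (res.assignment == 0).sum() == 5  # ceil(100 * 0.05)

    def test_alpha_zero_k1_is_gaussian_mle(self, rng):
        X = rng.multivariate_normal([1.0, -2.0], [[2.0, 0.3], [0.3, 1.0]], size=400)
        params = fo.TclustParams(k=1, alpha=0.0, restr_factor=1e6)
        res = fo.tclust_fit(
            X, params, init_at([X.mean(0)], [np.cov(X.T)], [1.0])
        )
        comp = res.components[0]
        np.testing.assert_allclose(comp.mean, X.mean(axis=0), atol=1e-8)
        # ML covariance (denominator n)
        centred = X - X.mean(axis=0)
        np.testing.assert_allclose(
            comp.cov, centred.T @ centred / len(X), atol=1e-8
        )

    def test_recovery_with_outliers(self):
        X, truth, means, covs, counts = three_gaussians_with_outliers(
            n=3000, outlier_frac=0.05
        )
        params = fo.TclustParams(k=3, alpha=0.05, restr_factor=100.0)
        res = fo.tclust_fit(X, params, init_at(means, covs, [0.5, 0.3, 0.2]))
        assert (res.assignment == 0).sum() == 150
        # match fitted clusters to generator components by their means
        fitted_means = np.stack([c.mean for c in res.components])
        D = ((fitted_means[:, None, :] - means[None, :, :]) ** 2).sum(-1)
        rows, cols = linear_sum_assignment(D)
        relabel = {r + 1: c + 1 for r, c in zip(rows, cols)}
        keep = (res.assignment > 0) & (truth > 0)
        mapped = np.array([relabel[j] for j in res.assignment[keep]])
        accuracy = (mapped == truth[keep]).mean()
        assert accuracy >= 0.95

    def test_objective_monotone(self):
        X, _, means, covs, _ = three_gaussians_with_outliers(n=800)
        params = fo.TclustParams(k=3, alpha=0.05, restr_factor=50.0)
        # deliberately bad init so the CEM must travel
        res = fo.tclust_fit(
            X, params,
            init_at(means + 3.0, [np.eye(2)] * 3, [1 / 3] * 3),
        )
        hist = res.objective_history
        assert len(hist) >= 2
        assert all(b >= a - 1e-6 for a, b in zip(hist, hist[1:]))

    def test_eig_ratio_bounded_every_m_step(self):
        X, _, means, covs, _ = three_gaussians_with_outliers(n=800)
        c = 5.0
        params = fo.TclustParams(k=3, alpha=0.05, restr_factor=c)
        res = fo.tclust_fit(X, params, init_at(means, covs, [0.5, 0.3, 0.2]))
        assert res.eig_ratio_history  # one entry per M-step
        assert all(r <= c * (1 + 1e-9) for r in res.eig_ratio_history)

    def test_too_few_events_rejected(self):
        params = fo.TclustParams(k=2, alpha=0.0)
        with pytest.raises(ValueError):
            fo.tclust_fit(
                np.zeros((5, 2)), params,
                init_at([[0, 0], [1, 1]], [np.eye(2)] * 2, [0.5, 0.5]),
            )


class TestTrimmedGaussianMixtureEstimator:
    def test_sklearn_conventions(self):
        X, _, _, _, _ = three_gaussians_with_outliers(n=600)
        est = fo.TrimmedGaussianMixture(k=3, alpha=0.05, random_state=0)
        labels = est.fit_predict(X)
        assert set(np.unique(labels)) <= {-1, 0, 1, 2}
        assert (labels == -1).sum() == 30  # ceil(600 * 0.05)
        assert est.result_.loglik == est.fit(X).result_.loglik  # deterministic

    def test_get_set_params(self):
        est = fo.TrimmedGaussianMixture(k=4)
        assert est.get_params()["k"] == 4
        est.set_params(alpha=0.1)
        assert est.alpha == 0.1


def template_from(means, covs, weights, labels=None, members=("m1",)):
    comps = [
        g(m, c, w, None if labels is None else labels[i])
        for i, (m, c, w) in enumerate(zip(means, covs, weights))
    ]
    return Template(
        mixture=fo.MixtureClustering(comps, id="tpl"),
        members=list(members),
        method="pooling" if labels else "kbarycenter",
    )


class TestBestUnsupervisedPartition:
    def test_matching_template_wins(self):
        X, _, means, covs, _ = three_gaussians_with_outliers(n=900)
        table = fo.EventTable(X, ["M1", "M2"], "t")
        good = template_from(means, covs, [0.5, 0.3, 0.2])
        bad = template_from(means + 40.0, covs, [0.5, 0.3, 0.2])
        params = fo.TclustParams(k=3, alpha=0.05)
        res_good, _ = fo.best_unsupervised_partition(table, [good], params)
        res_both, cu = fo.best_unsupervised_partition(table, [bad, good], params)
        assert res_both.loglik == pytest.approx(res_good.loglik)
        fitted = np.stack([c.mean for c in cu.components])
        D = ((fitted[:, None, :] - means[None, :, :]) ** 2).sum(-1)
        assert np.sqrt(D.min(axis=1)).max() < 1.0

    def test_external_partition_passthrough(self, rng):
        X = np.vstack([rng.normal(size=(50, 2)), rng.normal(size=(50, 2)) + 8])
        table = fo.EventTable(X, ["M1", "M2"], "t")
        ext = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
        res, cu = fo.best_unsupervised_partition(
            table, [], fo.TclustParams(k=2), external_partition=ext
        )
        assert res is None
        assert cu.n_components == 2
        np.testing.assert_allclose(cu.weights, [0.5, 0.5])


class TestAssignToTemplate:
    def test_identical_template_selected(self, rng):
        means = [[0.0, 0.0], [10.0, 0.0]]
        covs = [np.eye(2)] * 2
        cu = template_from(means, covs, [0.6, 0.4]).mixture
        t_match = template_from(means, covs, [0.6, 0.4])
        t_other = template_from([[50.0, 0.0], [60.0, 0.0]], covs, [0.5, 0.5])
        idx, dists = fo.assign_to_template(cu, [t_other, t_match])
        assert idx == 1
        assert dists[1] == pytest.approx(0.0, abs=1e-9)

    def test_single_template(self, rng):
        means = [[0.0, 0.0]]
        cu = template_from(means, [np.eye(2)], [1.0]).mixture
        idx, dists = fo.assign_to_template(cu, [template_from(means, [np.eye(2)], [1.0])])
        assert idx == 0 and len(dists) == 1


class TestClassifyEvents:
    def make_setup(self, seed=0):
        rng = np.random.default_rng(seed)
        means = np.array([[0.0, 0.0], [12.0, 0.0], [0.0, 12.0]])
        covs = [np.eye(2)] * 3
        weights = [0.5, 0.3, 0.2]
        labels = ["alpha", "beta", "gamma"]
        tpl = template_from(means, covs, weights, labels)
        counts = rng.multinomial(600, weights)
        X, truth = [], []
        for j, c in enumerate(counts):
            X.append(rng.multivariate_normal(means[j], covs[j], size=c))
            truth += [labels[j]] * c
        X = np.vstack(X)
        table = fo.EventTable(X, ["M1", "M2"], "t")
        params = fo.TclustParams(k=3, alpha=0.02)
        result, cu = fo.best_unsupervised_partition(table, [tpl], params)
        return table, tpl, result, cu, np.asarray(truth, dtype=object)

    def test_label_transfer_recovers_truth(self):
        table, tpl, result, cu, truth = self.make_setup()
        labels, trimmed, _ = fo.classify_events(
            table, cu, tpl, assignment=result.assignment,
            strategy="label_transfer",
        )
        assert trimmed.sum() == np.ceil(0.02 * table.n_events)
        assert (labels == truth).mean() > 0.98

    def test_qda_template_point_at_mean(self):
        tpl = template_from(
            [[0.0, 0.0], [10.0, 0.0]], [np.eye(2)] * 2, [0.5, 0.5], ["A", "B"]
        )
        table = fo.EventTable(np.array([[10.0, 0.0], [0.0, 0.0]]), ["M1", "M2"], "t")
        labels, _, _ = fo.classify_events(
            table, tpl.mixture, tpl, strategy="qda_template"
        )
        assert list(labels) == ["B", "A"]

    def test_qda_template_near_bayes_accuracy(self, rng):
        # sampled exactly from the template: QDA is the Bayes rule
        means = np.array([[0.0, 0.0], [4.0, 0.0]])
        tpl = template_from(means, [np.eye(2)] * 2, [0.5, 0.5], ["A", "B"])
        n = 4000
        comp = rng.integers(2, size=n)
        X = rng.standard_normal((n, 2)) + means[comp]
        truth = np.array(["A", "B"], dtype=object)[comp]
        table = fo.EventTable(X, ["M1", "M2"], "t")
        labels, _, _ = fo.classify_events(
            table, tpl.mixture, tpl, strategy="qda_template"
        )
        from scipy.stats import norm

        bayes = norm.cdf(2.0)  # P(correct) with unit-variance equal mixture
        acc = (labels == truth).mean()
        assert abs(acc - bayes) < 0.02

    def test_qda_nearest_trains_on_closest_member(self, rng):
        table, tpl, result, cu, truth = self.make_setup(seed=3)
        member_values = table.values + rng.normal(scale=0.01, size=table.values.shape)
        member = fo.GatedCytometry(
            fo.EventTable(member_values, ["M1", "M2"], "member1"), truth
        )
        labels, _, info = fo.classify_events(
            table, cu, tpl, assignment=result.assignment,
            group=[member], strategy="qda_nearest",
        )
        assert info["assigned_cytometry"] == "member1"
        assert (labels == truth).mean() > 0.98

    def test_unlabelled_template_rejected(self):
        tpl = template_from([[0.0, 0.0]], [np.eye(2)], [1.0])
        table = fo.EventTable(np.zeros((1, 2)), ["M1", "M2"], "t")
        with pytest.raises(ValueError):
            fo.classify_events(table, tpl.mixture, tpl, strategy="qda_template")

    @settings(deadline=None, max_examples=15)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_label_transfer_inverts_permutation(self, seed):
        """A permuted copy of the template is relabelled by the inverse map."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        means = rng.normal(scale=20.0, size=(k, 2))
        weights = rng.dirichlet(np.ones(k) * 8)
        labels = [f"L{i}" for i in range(k)]
        tpl = template_from(means, [np.eye(2)] * k, weights, labels)
        perm = rng.permutation(k)
        cu = fo.MixtureClustering(
            [g(means[j], np.eye(2), weights[j]) for j in perm], id="cu"
        )
        C = np.array(
            [[fo.gaussian_w2(a, b) for b in cu.components]
             for a in tpl.mixture.components]
        )
        coupling = fo.solve_ot(tpl.mixture.weights, cu.weights, C)
        mapping = fo.hard_relabel(fo.fuzzy_relabel(coupling), "hungarian")
        recovered = [mapping[l] for l in range(k)]
        np.testing.assert_array_equal(recovered, perm)


class TestEndToEnd:
    def test_target_assigned_to_its_group(self, synthetic_db):
        db, membership, params = synthetic_db
        target, truth = fo.generate_target(params, group=2, seed=77)
        labels, report = fo.optimal_flow_classification(
            target, db, cluster_method="complete", n_groups=3,
            template_method="pooling", strategy="label_transfer",
        )
        member_ids = set(report["assigned_members"])
        want = {c.id for c, m in zip(db, membership) if m == 2}
        assert member_ids == want
        assert fo.median_f_measure(truth, labels) >= 0.95

    def test_self_consistency_single_cytometry_database(self, rng):
        means = np.array([[0.0, 0.0], [14.0, 0.0], [0.0, 14.0]])
        comp = rng.integers(3, size=800)
        X = rng.standard_normal((800, 2)) + means[comp]
        labels_true = np.array(["a", "b", "c"], dtype=object)[comp]
        gated = fo.GatedCytometry(fo.EventTable(X, ["M1", "M2"], "only"), labels_true)
        # a database needs >= 2 entries to meta-cluster; duplicate the sample
        gated2 = fo.GatedCytometry(
            fo.EventTable(X + rng.normal(scale=0.01, size=X.shape), ["M1", "M2"], "dup"),
            labels_true,
        )
        pred, report = fo.optimal_flow_classification(
            fo.EventTable(X, ["M1", "M2"], "target"), [gated, gated2],
            cluster_method="complete", n_groups=1, template_method="pooling",
            strategy="qda_template",
        )
        assert (pred == labels_true).mean() > 0.99

    def test_marker_mismatch_rejected(self, synthetic_db):
        db, _, params = synthetic_db
        target, _ = fo.generate_target(params, group=0, seed=1)
        bad = fo.EventTable(target.values, ["X1", "X2"], "bad")
        clf = fo.TemplateGatingClassifier(
            cluster_method="complete", n_groups=3
        ).fit(db)
        with pytest.raises(DimensionMismatchError):
            clf.predict(bad)
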