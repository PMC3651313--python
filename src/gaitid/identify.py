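"""The three-step sensor-to-segment identification pipeline.

Step 1 assigns every sensor a segment *class* (pelvis, sternum, head,
shoulder, upper arm, forearm, hand, upper leg, lower leg, foot — without
left/right) with a decision tree over per-trial-ranked features.  Step 2
resolves left versus right for the paired proximal segments: of the two
upper-arm (upper-leg) candidates, the one whose vertical acceleration
correlates more strongly with the sternum (pelvis) roll angle is the right
one.  Step 3 propagates sides outward along the limb chains: each remaining
paired segment takes the side of the already-resolved neighbour with which
its designated acceleration component correlates most.

The final assignment is always either a bijection onto the configuration's
segments or an explicit flagged failure; step-1 predictions that violate the
configuration's class multiplicities are repaired by a maximum-likelihood
reassignment over the tree's leaf class frequencies, and every repair or
near-tie is flagged rather than silently accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import features as _feat
from . import preprocess as _pre
from . import treeclass as _tree
from .trial_io import (
    ConfigurationSpec,
    FeatureTable,
    SegmentLabel,
    Trial,
    full_body,
    get_configuration,
)

__all__ = [
    "IdentificationModel",
    "IdentificationResult",
    "train_pipeline",
    "identify_trial",
    "classify_step1",
    "classify_step2",
    "classify_step3",
    "evaluate",
    "evaluate_sensitivity",
    "TIE_TOLERANCE",
]

#: Absolute tolerance below which two correlation coefficients are
#: considered tied (the decision is then flagged as ambiguous).
TIE_TOLERANCE = 1e-6


@dataclass
class IdentificationModel:
    """A trained identification model: step-1 tree, step-2 rule (or tree),
    fixed step-3 component map, and the feature registry it was fit with."""

    config: ConfigurationSpec
    transform: str
    step1_tree: _tree.TreeNode
    class_names: list[str]
    feature_names: list[str]
    n_cycles_used: int = 3
    step2_mode: str = "rule"           # "rule" (published) or "tree"
    step2_tree: _tree.TreeNode | None = None
    step2_feature_names: list[str] | None = None

    def to_dict(self) -> dict:
        return {
            "config": {
                "name": self.config.name,
                "segments": [str(s) for s in self.config.segments],
            },
            "transform": self.transform,
            "n_cycles_used": self.n_cycles_used,
            "class_names": self.class_names,
            "feature_names": self.feature_names,
            "step1_tree": self.step1_tree.to_dict(),
            "step2_mode": self.step2_mode,
            "step2_tree": (
                self.step2_tree.to_dict() if self.step2_tree is not None else None
            ),
            "step2_feature_names": self.step2_feature_names,
            "step3_components": {
                k: list(v) for k, v in _feat.STEP3_COMPONENTS.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IdentificationModel":
        cfg = d["config"]
        return cls(
            config=get_configuration(cfg["name"], cfg.get("segments")),
            transform=d["transform"],
            step1_tree=_tree.TreeNode.from_dict(d["step1_tree"]),
            class_names=list(d["class_names"]),
            feature_names=list(d["feature_names"]),
            n_cycles_used=int(d.get("n_cycles_used", 3)),
            step2_mode=d.get("step2_mode", "rule"),
            step2_tree=(
                _tree.TreeNode.from_dict(d["step2_tree"])
                if d.get("step2_tree") is not None
                else None
            ),
            step2_feature_names=d.get("step2_feature_names"),
        )


@dataclass
class IdentificationResult:
    """The outcome of identifying one trial."""

    assignment: dict[str, SegmentLabel]
    step1_classes: dict[str, str]
    flags: list[str] = field(default_factory=list)
    success: bool = True

    @property
    def is_bijection(self) -> bool:
        return len(set(self.assignment.values())) == len(self.assignment)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_pipeline(
    trials: list[Trial],
    config: ConfigurationSpec | None = None,
    transform: str = "rank",
    n_cycles_used: int = 3,
    step2: str = "rule",
    seed: int = 0,
    **tree_params,
) -> IdentificationModel:
    """Train the step-1 tree (and optionally a step-2 tree) on labelled
    trials; step-3 rules are the fixed adjacent-segment component map."""
    if len(trials) < 2:
        raise ValueError("training requires at least 2 labelled trials")
    config = config or trials[0].config
    class_names = list(config.segment_classes)
    for t in trials:
        if t.labels is None:
            raise ValueError(f"trial {t.trial_id!r} has no labels")
        if t.config.segments != config.segments:
            raise ValueError("all training trials must share the configuration")

    pres = [
        _pre.preprocess_trial(t, n_cycles_used=n_cycles_used) for t in trials
    ]
    table = _feat.build_feature_table(pres, transform=transform)
    names = table.feature_names
    X = table.values.to_numpy()
    label_strings = list(table.labels)
    missing = set(class_names) - set(label_strings)
    if missing:
        raise ValueError(f"classes absent from training data: {sorted(missing)}")
    y = np.array([class_names.index(c) for c in label_strings])

    tree = _tree.build_tree(
        X, y, len(class_names), feature_names=names, **tree_params
    )

    step2_tree = None
    step2_names = None
    if step2 == "tree":
        step2_X, step2_y, step2_names = _step2_training_set(pres, config)
        step2_tree = _tree.build_tree(
            step2_X, step2_y, 2, feature_names=step2_names, **tree_params
        )
    elif step2 != "rule":
        raise ValueError(f"unknown step2 mode {step2!r}")

    return IdentificationModel(
        config=config,
        transform=transform,
        step1_tree=tree,
        class_names=class_names,
        feature_names=names,
        n_cycles_used=n_cycles_used,
        step2_mode=step2,
        step2_tree=step2_tree,
        step2_feature_names=step2_names,
    )


def _trunk_for(segment_class: str) -> str:
    """Which trunk sensor anchors the left/right call of a paired proximal
    segment: the sternum for the arms, the pelvis for the legs."""
    return "sternum" if segment_class == "upper_arm" else "pelvis"


def _step2_training_set(pres, config):
    """Ranked limb-versus-trunk correlation features with left/right labels,
    pooled over trials and over the paired proximal segment classes."""
    names = None
    rows, labels = [], []
    pair_classes = [
        c for c in ("upper_arm", "upper_leg") if c in config.segment_classes
    ]
    for pre in pres:
        t = pre.trial
        by_label = {str(lab): sid for sid, lab in t.labels.items()}
        for cls in pair_classes:
            trunk_sid = by_label[_trunk_for(cls)]
            theta = _feat.trunk_orientation(
                pre.signals[trunk_sid].gyr, pre.fs
            )
            feats = {}
            for side in ("left", "right"):
                sid = by_label[f"{side}_{cls}"]
                feats[side] = _feat.step2_features(pre.signals[sid], theta)
            if names is None:
                names = list(feats["left"])
            # rank each correlation feature within the candidate pair
            for side in ("left", "right"):
                ranked = [
                    float(
                        _feat.fractional_rank(
                            np.array(
                                [feats["left"][k], feats["right"][k]]
                            )
                        )[0 if side == "left" else 1]
                    )
                    for k in names
                ]
                rows.append(ranked)
                labels.append(0 if side == "left" else 1)
    return np.array(rows), np.array(labels), names


# ---------------------------------------------------------------------------
# Step 1
# ---------------------------------------------------------------------------

def classify_step1(
    model: IdentificationModel, table: FeatureTable
) -> tuple[dict[str, str], list[str]]:
    """Predict a segment class per sensor and enforce the configuration's
    class multiplicities.

    If the predicted class multiset violates the configuration (say three
    hands), sensors are re-assigned by maximizing the summed leaf class
    frequencies under the multiplicity constraints (a small assignment
    problem); any repair is flagged.
    """
    if len(table.values) != model.config.n_sensors:
        raise ValueError(
            f"trial has {len(table.values)} feature rows but configuration "
            f"declares {model.config.n_sensors}"
        )
    if list(table.values.columns) != model.feature_names:
        raise ValueError("feature table does not match the model's registry")
    X = table.values.to_numpy()
    pred = _tree.predict(model.step1_tree, X)
    sensor_ids = [sid for _, sid in table.values.index]
    classes = {sid: model.class_names[p] for sid, p in zip(sensor_ids, pred)}

    required = model.config.class_counts()
    observed: dict[str, int] = {}
    for c in classes.values():
        observed[c] = observed.get(c, 0) + 1
    flags: list[str] = []
    if observed != required:
        flags.append(
            "step1 multiplicity violation: "
            + ", ".join(
                f"{c}: {observed.get(c, 0)}/{required[c]}" for c in required
            )
        )
        # expand classes into capacity slots and solve the assignment
        slots: list[str] = []
        for c, k in required.items():
            slots.extend([c] * k)
        proba = np.array(
            [_tree.predict_proba(model.step1_tree, row) for row in X]
        )
        eps = 1e-9
        cost = np.array(
            [
                [-np.log(proba[i, model.class_names.index(c)] + eps) for c in slots]
                for i in range(len(X))
            ]
        )
        ri, ci = linear_sum_assignment(cost)
        classes = {sensor_ids[i]: slots[j] for i, j in zip(ri, ci)}
    return classes, flags


# ---------------------------------------------------------------------------
# Steps 2 and 3
# ---------------------------------------------------------------------------

def classify_step2(
    pre: _pre.PreprocessedTrial,
    candidates: tuple[str, str],
    trunk_sensor: str,
    segment_class: str,
    model: IdentificationModel | None = None,
) -> tuple[dict[str, str], list[str]]:
    """Resolve left/right for the two ``segment_class`` candidates.

    Published rule: the candidate whose vertical acceleration has the larger
    correlation with the trunk sensor's roll angle (orientation about x) is
    the right one.  A trained step-2 tree can be used instead when the model
    was fit with ``step2="tree"``.
    """
    theta = _feat.trunk_orientation(pre.signals[trunk_sensor].gyr, pre.fs)
    flags: list[str] = []
    if model is not None and model.step2_mode == "tree":
        feats = {
            sid: _feat.step2_features(pre.signals[sid], theta)
            for sid in candidates
        }
        names = model.step2_feature_names
        a, b = candidates
        rows = {}
        for sid, other in ((a, b), (b, a)):
            rows[sid] = [
                float(
                    _feat.fractional_rank(
                        np.array([feats[sid][k], feats[other][k]])
                    )[0]
                )
                for k in names
            ]
        pred = {
            sid: _tree.predict(model.step2_tree, np.array([rows[sid]]))[0]
            for sid in candidates
        }
        if pred[a] != pred[b]:
            sides = {a: "right" if pred[a] == 1 else "left"}
            sides[b] = "left" if sides[a] == "right" else "right"
            return sides, flags
        flags.append(f"step2 tree tied on {segment_class}; falling back to rule")
    cc = {
        sid: _feat._safe_corr(pre.signals[sid].acc[:, 2], theta[:, 0])
        for sid in candidates
    }
    a, b = candidates
    if abs(cc[a] - cc[b]) < TIE_TOLERANCE:
        flags.append(
            f"step2 ambiguous for {segment_class}: "
            f"cc difference {abs(cc[a] - cc[b]):.2e} below tolerance"
        )
    right = a if cc[a] >= cc[b] else b
    left = b if right == a else a
    return {right: "right", left: "left"}, flags


def classify_step3(
    pre: _pre.PreprocessedTrial,
    classes: dict[str, str],
    sides: dict[str, str],
) -> tuple[dict[str, str], list[str]]:
    """Propagate left/right outward along the limb chains.

    For each unresolved paired class, the two candidates are matched to the
    two resolved neighbours (on the component from the adjacency map) by
    choosing the pairing with the larger total correlation, which enforces a
    bijection by construction; near-ties are flagged.
    """
    flags: list[str] = []
    present = set(classes.values())
    for cls in _feat.STEP3_ORDER:
        if cls not in present:
            continue
        ref_cls = _feat.STEP3_COMPONENTS[cls][0]
        cand = sorted(sid for sid, c in classes.items() if c == cls)
        refs = {
            sides[sid]: sid
            for sid, c in classes.items()
            if c == ref_cls and sid in sides
        }
        if len(cand) != 2 or set(refs) != {"left", "right"}:
            raise ValueError(
                f"step3 needs two {cls} candidates and resolved {ref_cls} "
                "neighbours"
            )
        series = {
            sid: _feat.step3_component_series(pre.signals[sid], cls)
            for sid in cand + list(refs.values())
        }
        cc = {
            (u, side): _feat._safe_corr(series[u], series[refs[side]])
            for u in cand
            for side in ("left", "right")
        }
        # pairing A: cand0 left / cand1 right; pairing B: the swap
        score_a = cc[(cand[0], "left")] + cc[(cand[1], "right")]
        score_b = cc[(cand[0], "right")] + cc[(cand[1], "left")]
        if abs(score_a - score_b) < TIE_TOLERANCE:
            flags.append(f"step3 ambiguous for {cls}: pairing margin "
                         f"{abs(score_a - score_b):.2e} below tolerance")
        if score_a >= score_b:
            sides[cand[0]], sides[cand[1]] = "left", "right"
        else:
            sides[cand[0]], sides[cand[1]] = "right", "left"
    return sides, flags


# ---------------------------------------------------------------------------
# End-to-end identification
# ---------------------------------------------------------------------------

def identify_trial(
    model: IdentificationModel,
    trial: Trial,
    n_cycles_used: int | None = None,
    heading_offset: float = 0.0,
) -> IdentificationResult:
    """Identify every sensor of a trial with a trained model."""
    pre = _pre.preprocess_trial(
        trial,
        n_cycles_used=n_cycles_used or model.n_cycles_used,
        heading_offset=heading_offset,
    )
    raw = _feat.extract_trial_features(pre)
    table = _feat.transform_table(
        FeatureTable(raw, transform="raw"), model.transform
    )
    classes, flags = classify_step1(model, table)

    sides: dict[str, str] = {}
    # midline sensors carry no side
    by_class: dict[str, list[str]] = {}
    for sid, c in classes.items():
        by_class.setdefault(c, []).append(sid)

    for cls in ("upper_arm", "upper_leg"):
        if cls not in by_class:
            continue
        trunk_cls = _trunk_for(cls)
        trunk_sid = by_class[trunk_cls][0]
        cand = tuple(sorted(by_class[cls]))
        pair_sides, f2 = classify_step2(pre, cand, trunk_sid, cls, model)
        sides.update(pair_sides)
        flags.extend(f2)

    sides, f3 = classify_step3(pre, classes, sides)
    flags.extend(f3)

    assignment = {
        sid: SegmentLabel(c, sides.get(sid, "none")) for sid, c in classes.items()
    }
    ok = len(set(assignment.values())) == len(assignment) and sorted(
        assignment.values()
    ) == sorted(model.config.segments)
    if not ok:
        flags.append("assignment is not a bijection onto the configuration")
    return IdentificationResult(
        assignment=assignment,
        step1_classes=classes,
        flags=flags,
        success=ok,
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(
    model: IdentificationModel,
    trials: list[Trial],
    n_cycles_used: int | None = None,
    heading_offsets: list[float] | None = None,
) -> dict:
    """Step-wise accuracies of a fixed model on labelled trials.

    Step 1 counts correct segment classes over all sensors; step 2 counts
    correct sides on the paired proximal segments; step 3 on the distal
    ones; ``overall`` counts fully correct segment labels.
    """
    n1 = n1_ok = n2 = n2_ok = n3 = n3_ok = nall = nall_ok = 0
    n_flagged = 0
    step2_classes = {"upper_arm", "upper_leg"}
    confusion = np.zeros((len(model.class_names),) * 2, dtype=int)
    for i, trial in enumerate(trials):
        if trial.labels is None:
            raise ValueError(f"trial {trial.trial_id!r} has no labels")
        res = identify_trial(
            model,
            trial,
            n_cycles_used=n_cycles_used,
            heading_offset=(heading_offsets[i] if heading_offsets else 0.0),
        )
        n_flagged += bool(res.flags)
        for sid, true_label in trial.labels.items():
            pred_class = res.step1_classes[sid]
            n1 += 1
            n1_ok += pred_class == true_label.segment_class
            confusion[
                model.class_names.index(true_label.segment_class),
                model.class_names.index(pred_class),
            ] += 1
            pred_label = res.assignment[sid]
            nall += 1
            nall_ok += pred_label == true_label
            if true_label.side != "none" and pred_class == true_label.segment_class:
                correct_side = pred_label.side == true_label.side
                if true_label.segment_class in step2_classes:
                    n2 += 1
                    n2_ok += correct_side
                else:
                    n3 += 1
                    n3_ok += correct_side
    return {
        "n_sensors": n1,
        "step1_accuracy": n1_ok / n1,
        "step2_accuracy": n2_ok / n2 if n2 else float("nan"),
        "step3_accuracy": n3_ok / n3 if n3 else float("nan"),
        "overall_accuracy": nall_ok / nall,
        "n_trials_flagged": n_flagged,
        "confusion": confusion,
    }


def evaluate_sensitivity(
    model: IdentificationModel,
    trials: list[Trial],
    heading_sigma_deg: float = 0.0,
    seed: int = 0,
) -> dict:
    """Re-test a fixed model under heading perturbation.

    A random yaw error, one draw per trial from N(0, sigma), is added to the
    estimated walking-direction angle before the heading alignment; features
    are re-extracted and the unmodified model re-applied.
    """
    rng = np.random.default_rng(seed)
    offsets = [
        float(np.deg2rad(rng.normal(0.0, heading_sigma_deg)))
        if heading_sigma_deg > 0
        else 0.0
        for _ in trials
    ]
    return evaluate(model, trials, heading_offsets=offsets)
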