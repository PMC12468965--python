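"""Render MetricReport contents to PNG plots and CSV point lists."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def _as_dict(report):
    if hasattr(report, "to_dict"):
        return report.to_dict()
    return report


def render_report(report, out_dir, name="run"):
    """Write ROC/PR/calibration/decision-curve plots plus CSV point
    lists and a confusion-matrix heatmap for one evaluation report."""
    rep = _as_dict(report)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    curves = rep.get("curves", {})

    if "roc" in curves:
        fpr = np.asarray(curves["roc"]["fpr"], dtype=float)
        tpr = np.asarray(curves["roc"]["tpr"], dtype=float)
        pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
            out / f"{name}_roc.csv", index=False)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(fpr, tpr, label=f"AUC = {rep.get('auc', float('nan')):.3f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        fig.savefig(out / f"{name}_roc.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written += [f"{name}_roc.png", f"{name}_roc.csv"]

    if "pr" in curves:
        prec = np.asarray(curves["pr"]["precision"], dtype=float)
        recall = np.asarray(curves["pr"]["recall"], dtype=float)
        pd.DataFrame({"precision": prec, "recall": recall}).to_csv(
            out / f"{name}_pr.csv", index=False)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(recall, prec)
        ax.set_xlabel("Recall")
        ax.set_ylabel("Precision")
        fig.savefig(out / f"{name}_pr.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written += [f"{name}_pr.png", f"{name}_pr.csv"]

    if "calibration" in curves:
        cal = pd.DataFrame(curves["calibration"])
        cal.to_csv(out / f"{name}_calibration.csv", index=False)
        occupied = cal[cal["count"] > 0]
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.plot(occupied["mean_predicted"], occupied["observed_frequency"],
                "o-")
        ax.set_xlabel("Mean predicted probability")
        ax.set_ylabel("Observed frequency")
        fig.savefig(out / f"{name}_calibration.png", dpi=120,
                    bbox_inches="tight")
        plt.close(fig)
        written += [f"{name}_calibration.png", f"{name}_calibration.csv"]

    if "decision" in curves:
        dca = pd.DataFrame(curves["decision"])
        dca.to_csv(out / f"{name}_decision.csv", index=False)
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.plot(dca["threshold"], dca["net_benefit_model"], label="model")
        ax.plot(dca["threshold"], dca["net_benefit_treat_all"],
                label="treat all")
        ax.plot(dca["threshold"], dca["net_benefit_treat_none"],
                label="treat none")
        ax.set_ylim(bottom=-0.1)
        ax.set_xlabel("Threshold probability")
        ax.set_ylabel("Net benefit")
        ax.legend()
        fig.savefig(out / f"{name}_decision.png", dpi=120,
                    bbox_inches="tight")
        plt.close(fig)
        written += [f"{name}_decision.png", f"{name}_decision.csv"]

    if rep.get("confusion"):
        labels = sorted(rep["confusion"])
        # binary: rebuild the 2x2 matrix from the positive-class counts
        cm = rep["confusion"][labels[-1]]
        mat = np.array([[cm["tn"], cm["fp"]], [cm["fn"], cm["tp"]]])
        pd.DataFrame(mat, index=labels, columns=labels).to_csv(
            out / f"{name}_confusion.csv")
        fig, ax = plt.subplots(figsize=(3.5, 3.2))
        ax.imshow(mat, cmap="Blues")
        for i in range(2):
            for j in range(2):
                ax.text(j, i, str(mat[i, j]), ha="center", va="center")
        ax.set_xticks([0, 1], labels, rotation=30, ha="right")
        ax.set_yticks([0, 1], labels)
        ax.set_xlabel("Predicted")
        ax.set_ylabel("True")
        fig.savefig(out / f"{name}_confusion.png", dpi=120,
                    bbox_inches="tight")
        plt.close(fig)
        written += [f"{name}_confusion.png", f"{name}_confusion.csv"]
    return written


def render_report_file(report_json, out_dir):
    with open(report_json) as fh:
        rep = json.load(fh)
    return render_report(rep, out_dir, name=Path(report_json).stem)
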