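"""Markdown report assembly for a complete survey analysis run."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

__all__ = ["build_report"]

_HEADER = "# Subjective evidence evaluation report\n"


def _consensus_section(fit_dir: Path) -> str:
    lines = ["## Consensus\n"]
    found = False
    for csv in sorted(fit_dir.glob("summary_*.csv")):
        found = True
        subscale = csv.stem.replace("summary_", "")
        lines.append(f"### {subscale}\n")
        rows = csv.read_text().strip().splitlines()
        header = rows[0].split(",")
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))
        for row in rows[1:]:
            lines.append("| " + " | ".join(row.split(",")) + " |")
        meta = fit_dir / f"overall_{subscale}.json"
        if meta.exists():
            o = json.loads(meta.read_text())
            lines.append(
                f"\nOverall consensus: {o['overall_median']:.2f} "
                f"[{o['overall_ci'][0]:.2f}, {o['overall_ci'][1]:.2f}], "
                f"item SD {o['sd_across_items']:.2f}\n"
            )
        png = fit_dir / f"forest_{subscale}.png"
        if png.exists():
            lines.append(f"![forest plot {subscale}]({png.name})\n")
    if not found:
        lines.append("*Section unavailable: no fit outputs found.*\n")
    return "\n".join(lines) + "\n"


def _beliefs_section(beliefs_json: Path | None) -> str:
    lines = ["## Belief updating\n"]
    if beliefs_json is None or not beliefs_json.exists():
        lines.append("*Section unavailable: no beliefs input.*\n")
        return "\n".join(lines) + "\n"
    b = json.loads(beliefs_json.read_text())
    lines += [
        f"- Mean plausibility: {b['mean_prior']:.2f} -> {b['mean_final']:.2f}",
        f"- Agreement: {b['pct_agree_prior']:.2f}% -> {b['pct_agree_final']:.2f}%",
        f"- Belief change: {b['prop_increased']:.0%} increased, "
        f"{b['prop_decreased']:.0%} decreased, {b['prop_unchanged']:.0%} unchanged "
        f"(n = {b['n_complete']})",
    ]
    return "\n".join(lines) + "\n"


def _correlation_section(corr_json: Path | None) -> str:
    lines = ["## Correlations with outcome metrics\n"]
    if corr_json is None or not corr_json.exists():
        lines.append("*Section unavailable: no correlation input.*\n")
        return "\n".join(lines) + "\n"
    results = json.loads(corr_json.read_text())
    if isinstance(results, dict):
        results = [results]
    lines.append("| method | n | estimate | 95% CI | BF+0 | BF0+ |")
    lines.append("|---|---|---|---|---|---|")
    for r in results:
        lines.append(
            f"| {r['method']} | {r['n']} | {r['estimate']:.2f} "
            f"| [{r['ci_lower']:.2f}, {r['ci_upper']:.2f}] "
            f"| {r['bf_plus0']:.2f} | {r['bf_0plus']:.2f} |"
        )
    return "\n".join(lines) + "\n"


def build_report(
    fit_dir: str | Path,
    out_path: str | Path,
    beliefs_json: str | Path | None = None,
    corr_json: str | Path | None = None,
    metadata: dict | None = None,
) -> Path:
    """Assemble a self-contained Markdown report from run outputs.

    Missing inputs produce sections marked unavailable rather than
    failures, so partial pipelines still document what they did.
    """
    fit_dir = Path(fit_dir)
    out_path = Path(out_path)
    parts = [_HEADER]
    if metadata:
        parts.append(
            "Run metadata: "
            + ", ".join(f"{k}={v}" for k, v in sorted(metadata.items()))
            + "\n"
        )
    parts.append(_consensus_section(fit_dir))
    parts.append(_beliefs_section(Path(beliefs_json) if beliefs_json else None))
    parts.append(_correlation_section(Path(corr_json) if corr_json else None))
    parts.append(
        f"\n---\nGenerated {datetime.now(timezone.utc).isoformat(timespec='seconds')}\n"
    )
    out_path.write_text("\n".join(parts), encoding="utf-8")
    return out_path
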