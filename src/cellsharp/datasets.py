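"""On-disk layout for paired datasets.

A dataset directory holds ``<stem>__input.png`` / ``<stem>__target.png``
pairs plus a ``manifest.json`` recording the generating specs and seeds, so
a written dataset can be reproduced or reloaded exactly (up to the 8/16-bit
quantisation of the files).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from .image_io import read_image, write_image
from .synthetic_cells import DegradationSpec, PairedDataset

__all__ = ["save_dataset", "load_dataset"]


def save_dataset(dataset: PairedDataset, out_dir: str | Path,
                 bit_depth: int = 16, extra_meta: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (inp, tgt) in enumerate(dataset.pairs):
        stem = f"pair{i:05d}"
        write_image(inp, out_dir / f"{stem}__input.png", bit_depth)
        write_image(tgt, out_dir / f"{stem}__target.png", bit_depth)
        prov = dataset.provenance[i] if i < len(dataset.provenance) else None
        entries.append({
            "stem": stem,
            "pixel_size": inp.pixel_size,
            "degradation": asdict(prov) if prov is not None else None,
        })
    manifest = {"target_mode": dataset.target_mode, "bit_depth": bit_depth,
                "n_pairs": len(dataset), "pairs": entries}
    manifest.update(extra_meta or {})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def load_dataset(path: str | Path) -> PairedDataset:
    path = Path(path)
    manifest_path = path / "manifest.json" if path.is_dir() else path
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    pairs = []
    provenance = []
    for entry in manifest["pairs"]:
        stem = entry["stem"]
        inp = read_image(root / f"{stem}__input.png", pixel_size=entry.get("pixel_size", 0.65))
        tgt = read_image(root / f"{stem}__target.png", pixel_size=entry.get("pixel_size", 0.65))
        pairs.append((inp, tgt))
        if entry.get("degradation"):
            provenance.append(DegradationSpec(**entry["degradation"]))
    return PairedDataset(pairs=pairs, target_mode=manifest.get("target_mode", "GT"),
                         provenance=provenance)
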