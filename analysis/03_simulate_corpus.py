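"""Simulate a labeled training corpus of SNP images at reduced scale.

Builds the 3-model contrast (distance vs. strong slope vs. strong rivers)
on the 12-deme layout, simulates n examples per model, encodes them as
binary images, and writes the image archive, the provenance manifest and one
example VCF to results/corpus/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from landcnn.encoding import save_images
from landcnn.experiments import (
    build_training_corpus,
    reduced_design,
    reduced_landscape,
    selfclass_models,
)
from landcnn.resistance import build_migration_schedule
from landcnn.simulate import sample_parameters, simulate_genotypes, write_vcf


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-per-model", type=int, default=100)
    ap.add_argument("--n-snps", type=int, default=500)
    ap.add_argument("--out", type=Path, default=Path("results/corpus"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(args.seed)
    s_land, s_corpus, s_vcf = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
    landscape = reduced_landscape(s_land)
    design = reduced_design(n_snps=args.n_snps, strong=True)
    models = selfclass_models()

    images, manifest = build_training_corpus(
        design, landscape, models, args.n_per_model, seed=s_corpus
    )
    save_images(images, out / "corpus.npz")
    (out / "manifest.json").write_text(json.dumps(
        {"seed": args.seed, "n_per_model": args.n_per_model,
         "n_snps": args.n_snps, "examples": manifest}, indent=2))
    landscape.demes.to_tsv(out / "demes.tsv")

    # one example dataset as VCF for inspection
    model = models[0]
    draw = sample_parameters(design, model, np.random.default_rng(s_vcf))
    sched = build_migration_schedule(
        model, landscape.stacks, draw.effect_weights, draw.dispersal, landscape.demes
    )
    g = simulate_genotypes(design, landscape.demes, draw, sched, label=model.id)
    write_vcf(g, out / "example_model1.vcf")

    labels = [im.label for im in images]
    print(f"Simulated {len(images)} images "
          f"({args.n_per_model}/model over models {sorted(set(labels))}), "
          f"shape {images[0].shape} (sequences x SNPs).")
    print(f"Wrote corpus.npz, manifest.json and example_model1.vcf to {out}/")


if __name__ == "__main__":
    main()
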