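"""Train the small CNN on a surrogate line-identity task and reuse its
penultimate layer as an image embedding."""
from morphomap.profiling import CNNConfig, train_feature_extractor
from morphomap.synth import generate_cohort

cohort = generate_cohort({"clump": 40, "tree_like": 40}, jitter=0.1, seed=5)
extractor = train_feature_extractor(cohort.images, cohort.lines,
                                    CNNConfig(epochs=8, seed=0))
for rec in extractor.history[-3:]:
    print(f"epoch {rec['epoch']:2d}  loss {rec['train_loss']:.3f}  "
          f"val accuracy {rec['val_accuracy']:.2f}")
embedding = extractor.features(cohort.images)
print(f"penultimate embedding: {embedding.shape[0]} organoids x "
      f"{embedding.shape[1]} dimensions")
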