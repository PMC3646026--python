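# Mammography profile: calcification, breast-shape and texture features.
# Weights rebalance the very different field scales (area is in pixels,
# texture statistics are order 1).
name: mammo
modalities: ["MG"]
features:
  - calcCount
  - breastArea
  - breastEdgeAngle
  - textureContrast
  - textureCorrelation
  - textureEnergy
  - textureHomogeneity
  - edgeHistogram
metric:
  name: euclidean
  params:
    weights:
      calcCount: 1.0
      breastArea: 1.0e-6
      breastEdgeAngle: 0.01
      textureContrast: 1.0
      textureCorrelation: 1.0
      textureEnergy: 1.0
      textureHomogeneity: 1.0
      edgeHistogram: 1.0
box:
  kind: k_sigma
  params:
    k_sigma: 2.0
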