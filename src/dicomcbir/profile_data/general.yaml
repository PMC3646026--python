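# Catch-all profile: global features under an unweighted Euclidean metric.
name: general
modalities: ["*"]
features:
  - intensityHistogram
  - entropy
  - edgeHistogram
  - huMoment
metric:
  name: euclidean
  params: {}
box:
  kind: k_sigma
  params:
    k_sigma: 2.0
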