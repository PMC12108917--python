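# The ten packaged case-study scenarios: Huntington's disease (HTT),
# amyotrophic lateral sclerosis (SOD1 / FUS / C9orf72) and phenylketonuria
# (PAH).  All probabilities are plain decimals; 95% confidence intervals are
# attached where newly derived estimates carry them.
scenarios:
  - label: "HTT (screening)"
    variant_type: STRE
    prior_disease: 0.000410
    marker_freq_affected: 1.0
    penetrance: 1.0
    test: {sensitivity: 0.990, specificity: 0.900, label: "STRE calling (short-read)"}

  - label: "HTT (targeted)"
    variant_type: STRE
    prior_disease: 0.500
    marker_freq_affected: 1.0
    penetrance: 1.0
    test: {sensitivity: 0.990, specificity: 0.900, label: "STRE calling (short-read)"}

  - label: "SOD1 (all)"
    variant_type: SNV
    prior_disease: 0.00333
    marker_freq_affected: 0.0188
    penetrance: 0.701
    test: {sensitivity: 0.9996, specificity: 0.9995, label: "SNV calling"}
    intervals:
      marker_freq_affected: {point: 0.0188, lower: 0.0138, upper: 0.0238}
      penetrance: {point: 0.701, lower: 0.491, upper: 0.926}

  - label: "SOD1 (A5V)"
    variant_type: SNV
    prior_disease: 0.00333
    marker_freq_affected: 0.000529
    penetrance: 0.91
    test: {sensitivity: 0.9996, specificity: 0.9995, label: "SNV calling"}
    intervals:
      marker_freq_affected: {point: 0.000529, lower: 4.43e-5, upper: 0.00101}

  - label: "FUS (all)"
    variant_type: SNV
    prior_disease: 0.00333
    marker_freq_affected: 0.00425
    penetrance: 0.579
    test: {sensitivity: 0.9996, specificity: 0.9995, label: "SNV calling"}
    intervals:
      marker_freq_affected: {point: 0.00425, lower: 0.0023, upper: 0.0062}
      penetrance: {point: 0.579, lower: 0.291, upper: 0.884}

  - label: "FUS (ClinVar)"
    variant_type: SNV
    prior_disease: 0.00333
    marker_freq_affected: 0.00251
    penetrance: 0.536
    test: {sensitivity: 0.9996, specificity: 0.9995, label: "SNV calling"}
    intervals:
      marker_freq_affected: {point: 0.00251, lower: 0.00125, upper: 0.00377}
      penetrance: {point: 0.536, lower: 0.211, upper: 0.877}

  - label: "C9orf72 (screening)"
    variant_type: STRE
    prior_disease: 0.00333
    marker_freq_affected: 0.0635
    penetrance: 0.439
    test: {sensitivity: 0.990, specificity: 0.900, label: "STRE calling (short-read)"}
    intervals:
      marker_freq_affected: {point: 0.0635, lower: 0.0538, upper: 0.0732}
      penetrance: {point: 0.439, lower: 0.358, upper: 0.520}

  - label: "C9orf72 (confirmation)"
    variant_type: STRE
    prior_disease: 0.00333
    marker_freq_affected: 0.0635
    penetrance: 0.439
    test: {sensitivity: 0.990, specificity: 0.900, label: "STRE calling (short-read)"}
    confirmatory_tests:
      - {sensitivity: 0.95, specificity: 0.98, label: "repeat-primed PCR"}

  - label: "PAH (screening)"
    variant_type: SNV
    prior_disease: 0.000100
    marker_freq_affected: 0.743
    penetrance: 0.892
    test: {sensitivity: 0.9996, specificity: 0.9995, label: "SNV calling"}

  - label: "PAH (confirmation)"
    variant_type: SNV
    prior_disease: 0.000100
    marker_freq_affected: 0.743
    penetrance: 0.892
    test: {sensitivity: 0.9996, specificity: 0.9995, label: "SNV calling"}
    # prior after a positive metabolic (tandem mass spectrometry) screen is
    # 1/6 (printed 0.167); risk after a negative metabolic screen ~1e-6
    external_prior: 0.16666666666666666
    external_negative_risk: 1.0e-6
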