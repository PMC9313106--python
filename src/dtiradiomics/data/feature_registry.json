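{
  "version": 1,
  "description": "Per-class texture/histogram feature registry. 92 features per image form; with the default 25-form transform manifest this yields 2300 features per scalar map and 4600 per subject (FA + MD).",
  "classes": {
    "Histogram": [
      "Mean", "Median", "Minimum", "Maximum", "Range",
      "Percentile10", "Percentile25", "Percentile75", "Percentile90",
      "InterquartileRange", "Variance", "StandardDeviation", "Skewness",
      "Kurtosis", "Energy", "TotalEnergy", "RootMeanSquared",
      "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
      "MedianAbsoluteDeviation", "CoefficientOfVariation",
      "Entropy", "Uniformity"
    ],
    "GLCM": [
      "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
      "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
      "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
      "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
      "MCC", "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares"
    ],
    "GLRLM": [
      "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
      "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
      "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
      "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
      "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
      "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
      "LongRunHighGrayLevelEmphasis"
    ],
    "GLSZM": [
      "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
      "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
      "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
      "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
      "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
      "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
      "LargeAreaHighGrayLevelEmphasis"
    ],
    "GLDM": [
      "SmallDependenceEmphasis", "LargeDependenceEmphasis",
      "GrayLevelNonUniformity", "DependenceNonUniformity", "GrayLevelVariance",
      "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
      "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
      "SmallDependenceHighGrayLevelEmphasis",
      "LargeDependenceLowGrayLevelEmphasis",
      "LargeDependenceHighGrayLevelEmphasis"
    ]
  }
}
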