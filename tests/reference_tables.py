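"""Published benchmark metric columns used as regression fixtures.

Each column is one classifier configuration's ten reported metrics (percent,
two decimals). Used to check internal consistency of the metric definitions:
the rate/complement identities must hold within printed rounding precision.
"""

BENCHMARK_COLUMNS_A = {
    "GWO": dict(accuracy=92.80, sensitivity=100.00, specificity=92.12, precision=54.43,
                FPR=7.88, FNR=0.00, NPV=92.12, FDR=45.57, F1=70.49, MCC=70.81),
    "DA": dict(accuracy=94.00, sensitivity=98.84, specificity=93.55, precision=59.03,
               FPR=6.46, FNR=1.16, NPV=93.55, FDR=40.97, F1=73.91, MCC=73.77),
    "DOX": dict(accuracy=95.40, sensitivity=98.84, specificity=95.08, precision=65.39,
                FPR=4.92, FNR=1.16, NPV=95.08, FDR=34.62, F1=78.70, MCC=78.29),
    "SFO-TSA": dict(accuracy=96.70, sensitivity=100.00, specificity=96.39, precision=72.27,
                    FPR=3.61, FNR=0.00, NPV=96.39, FDR=27.73, F1=83.90, MCC=83.46),
    "TS-SFO-RNN": dict(accuracy=96.89, sensitivity=75.00, specificity=98.12, precision=69.23,
                       FPR=1.88, FNR=25.00, NPV=98.12, FDR=30.77, F1=72.00, MCC=70.42),
    "IDOX": dict(accuracy=97.70, sensitivity=98.84, specificity=97.59, precision=79.44,
                 FPR=2.41, FNR=1.16, NPV=97.59, FDR=20.56, F1=88.08, MCC=87.46),
}

BENCHMARK_COLUMNS_B = {
    "NN": dict(accuracy=94.70, sensitivity=100.00, specificity=94.20, precision=61.87,
               FPR=5.80, FNR=0.00, NPV=94.20, FDR=38.13, F1=76.44, MCC=76.34),
    "KNN": dict(accuracy=94.80, sensitivity=100.00, specificity=94.31, precision=62.32,
                FPR=5.69, FNR=0.00, NPV=94.31, FDR=37.68, F1=76.79, MCC=76.66),
    "LSTM": dict(accuracy=92.60, sensitivity=100.00, specificity=91.90, precision=53.75,
                 FPR=8.10, FNR=0.00, NPV=91.90, FDR=46.25, F1=69.92, MCC=70.28),
    "BiLSTM": dict(accuracy=95.10, sensitivity=98.84, specificity=94.75, precision=63.91,
                   FPR=5.25, FNR=1.16, NPV=94.75, FDR=36.09, F1=77.63, MCC=77.27),
    "TS-SFO-RNN": dict(accuracy=96.89, sensitivity=75.00, specificity=98.12, precision=69.23,
                       FPR=1.88, FNR=25.00, NPV=98.12, FDR=30.77, F1=72.00, MCC=70.42),
    "IDOX": dict(accuracy=97.70, sensitivity=98.84, specificity=97.59, precision=79.44,
                 FPR=2.41, FNR=1.16, NPV=97.59, FDR=20.56, F1=88.08, MCC=87.46),
}

#: headline lower bounds (the "IDOX" column of the benchmark tables, percent)
HEADLINE = dict(accuracy=97.70, sensitivity=98.84, specificity=97.59, precision=79.44)
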