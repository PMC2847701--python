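# Recurrence risks to relatives for common complex genetic diseases, ordered by prevalence.
# Raw columns: prevalence K and recurrence risk ratios lambda_mz, lambda_sib, lambda_op
# (empty where no published estimate).  *_printed columns are the summary values as
# printed in the published compilation (kept verbatim, including their rounding):
# h2_01 = (lambda_mz-1)K/(1-K); dominance_ratio = (lambda_sib-1)/(lambda_op-1);
# excess_ratio = (lambda_mz-1)/(lambda_sib-1); mz_over_sib_sq = lambda_mz/lambda_sib^2;
# h2_liability = liability-scale heritability inferred from MZ concordance.
disease	K	lambda_mz	lambda_sib	lambda_op	h2_01_printed	dominance_ratio_printed	excess_ratio_printed	mz_over_sib_sq_printed	h2_liability_printed
Major depression	0.24	2	1.3		0.32		3.3	1.2	0.34
Age-related macular degeneration	0.12	4.7	2.1		0.50		3.4	1.1	0.64
Myocardial infarction	0.056	4.6	3.2		0.21		1.6	0.4	0.72
Breast cancer	0.036	4.1	2.2	1.9	0.12	1.3	2.6	0.8	0.37
Type II diabetes	0.028	10.4	3.5		0.27		3.8	0.8	0.58
Asthma	0.019	6.6	3.4		0.11		2.3	0.6	0.49
Rheumatoid arthritis	0.01	12.2	3.6		0.11		4.3	0.9	0.42
Bipolar disorder	0.01	60	7	7	0.60	1.0	10	1.2	0.70
Schizophrenia	0.0085	52.1	8.6	10	0.44	0.8	6.7	0.7	0.76
Type I diabetes	0.005	79	14		0.39		6.0	0.4	0.85
Multiple sclerosis	0.001	190	20		0.19	1	9.9	0.5	0.68
Crohn's disease	0.001	600	64		0.60		10	0.1	1.00
Ankylosing spondylitis	0.001	630	82	79	0.63	1.0	7.8	0.1	1.00
Systemic lupus erythematosus	0.001		29	27		1.1			0.80
Autism	0.0003	774	65		0.24		12	0.2	0.84
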