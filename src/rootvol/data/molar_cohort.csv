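case_id,pr_mesial_length_mm,pr_mesial_width_mm,pr_distal_length_mm,pr_distal_width_mm,cbct_mesial_length_mm,cbct_mesial_width_mm,cbct_distal_length_mm,cbct_distal_width_mm,true_volume_mm3,pr_surface_mm2,cbct_surface_mm2,projection_factor,applied_volume_pr_mm3,cuboid_volume_cbct_mm3
case01,11.06,2.53,11.97,2.52,12.13,3.88,10.61,3.49,389.73,45.67,66.05,8.53,352.56,362.22
case02,12.06,2.88,10.40,3.59,13.74,2.57,10.85,4.07,573.76,56.60,62.48,10.14,436.97,412.76
case03,16.66,3.96,15.90,4.20,16.07,4.02,15.17,4.52,739.55,104.26,104.51,7.09,804.92,711.01
case04,12.44,3.91,12.90,3.29,14.16,3.02,14.83,3.70,601.36,71.54,76.69,8.41,552.25,559.66
case05,14.50,4.58,13.44,3.72,13.82,4.63,13.12,4.64,662.27,91.43,98.03,7.24,705.81,712.38
case06,11.69,3.14,11.58,3.86,12.81,3.39,12.76,3.53,493.58,63.94,69.54,7.72,493.58,452.20
case07,13.00,4.30,13.78,5.11,12.61,4.54,13.81,5.36,554.57,99.21,103.05,5.59,765.89,781.99
case08,12.72,3.51,12.16,3.51,12.84,3.91,11.57,5.33,516.09,68.59,87.83,7.52,529.50,569.44
case09,10.43,5.07,7.11,3.30,11.82,4.26,11.12,4.42,516.16,59.96,78.17,8.61,462.89,704.22
case10,8.52,3.49,7.38,3.95,9.03,4.54,8.76,3.28,356.85,46.25,54.71,7.72,357.04,581.22
case11,11.34,4.27,13.84,4.07,13.46,5.89,13.55,6.08,784.24,82.27,126.97,9.53,635.13,1082.90
case12,10.06,3.03,10.80,3.58,11.10,4.06,10.07,4.40,331.67,54.31,70.21,6.11,419.25,429.02
case13,7.62,2.60,9.77,2.88,10.37,3.23,10.11,2.65,334.43,37.66,47.33,8.88,290.73,361.77
case14,8.72,3.01,6.06,2.99,10.90,4.09,6.98,3.98,305.62,34.85,56.82,8.77,269.01,456.39
case15,11.91,3.88,9.11,2.82,8.75,3.03,8.61,2.24,301.32,56.47,35.97,5.34,435.96,264.77
case16,9.37,3.06,8.50,2.33,8.87,3.33,10.01,3.77,324.38,38.07,52.80,8.52,293.93,492.42
case17,11.98,4.50,13.73,4.52,11.57,2.69,11.79,3.52,391.86,91.08,56.96,4.30,703.16,395.71
case18,9.64,3.09,8.45,2.94,7.95,3.84,9.72,4.59,450.22,42.91,59.00,10.49,331.24,463.26
case19,9.10,3.34,8.59,3.86,14.16,4.17,12.33,3.93,515.02,49.91,84.36,10.32,385.33,627.33
case20,10.06,4.65,8.36,3.62,10.71,3.56,9.00,3.55,402.53,60.51,55.06,6.65,467.13,533.58
case21,10.43,4.47,9.02,2.43,11.83,3.05,9.16,3.59,421.40,53.83,54.23,7.83,415.58,389.20
case22,12.31,3.07,9.56,2.61,12.14,3.26,10.76,4.07,400.14,49.28,65.47,8.12,380.43,437.77
case23,8.97,2.99,8.39,3.96,9.93,2.71,10.54,3.62,308.38,47.16,51.12,6.54,364.07,625.69
case24,9.75,3.48,8.95,3.26,9.66,3.30,12.63,3.07,511.06,49.56,55.49,10.31,382.64,566.75
case25,9.86,7.77,9.38,3.02,10.90,4.00,11.17,3.80,502.55,82.42,67.58,6.10,636.28,599.96
case26,8.37,2.99,7.47,3.28,10.17,3.32,8.34,3.66,518.34,38.90,50.49,13.33,300.30,306.49
case27,12.72,3.43,12.23,4.29,12.71,4.14,12.19,3.67,559.49,75.47,76.46,7.41,582.66,615.93
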