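	Reading 1	Reading 2	Reading 3	Reading 4
Timestamp_RAW	11,461,017.00	11,467,417.00	11,473,817.00	11,480,217.00
Timestamp_CAL	189,443.36	189,638.67	189,833.98	190,029.30
Low_Noise_Accelerometer_X_RAW	2006.00	2006.00	2007.00	2006.00
Low_Noise_Accelerometer_X_CAL	2.05	2.08	2.05	2.07
Low_Noise_Accelerometer_Y_RAW	2064.00	2062.00	2064.00	2063.00
Low_Noise_Accelerometer_Y_CAL	2.68	2.68	2.67	2.68
Low_Noise_Accelerometer_Z_RAW	1219.00	1218.00	1220.00	1221.00
Low_Noise_Accelerometer_Z_CAL	11.24	11.25	11.23	11.22
Wide_Range_Accelerometer_X_RAW	16.00	52.00	48.00	36.00
Wide_Range_Accelerometer_X_CAL	−0.63	−0.63	−0.65	−0.57
Wide_Range_Accelerometer_Y_RAW	−1060.00	−1056.00	−1088.00	−960.00
Wide_Range_Accelerometer_Y_CAL	−0.01	−0.03	−0.03	−0.02
Wide_Range_Accelerometer_Z_RAW	−17,352.00	−17,336.00	−17,352.00	−17,316.00
Wide_Range_Accelerometer_Z_CAL	10.38	10.37	10.38	10.36
Gyroscope_X_RAW	−24.00	−14.00	−20.00	−9.00
Gyroscope_X_CAL	−0.66	−1.19	−1.08	−0.81
Gyroscope_Y_RAW	43.00	78.00	71.00	53.00
Gyroscope_Y_CAL	0.37	0.21	0.31	0.14
Gyroscope_Z_RAW	−11.00	−8.00	−4.00	3.00
Gyroscope_Z_CAL	0.17	0.12	0.06	−0.05
Magnetometer_X_RAW	1023.00	1791.00	−2.00	1535.00
Magnetometer_X_CAL	14.58	20.73	13.82	17.27
Magnetometer_Y_RAW	9728.00	13,824.00	9216.00	11,520.00
Magnetometer_Y_CAL	−1.53	−2.69	0.00	−2.30
Magnetometer_Z_RAW	23,297.00	21,761.00	19,457.00	22,273.00
Magnetometer_Z_CAL	−34.93	−32.63	−29.17	−33.39
Pressure_RAW	20,384.00	20,385.00	20,385.00	20,384.00
Pressure_CAL	10,514.43	10,515.09	10,515.09	10,514.43
Temperature_RAW	32,862.00	32,862.00	32,862.00	32,862.00
Temperature_CAL	8.06	8.06	8.06	8.06
Axis_Angle_A_CAL	0.07	0.07	0.09	0.08
Axis_Angle_X_CAL	−0.14	−0.04	−0.02	0.14
Axis_Angle_Y_CAL	0.83	0.81	0.72	0.76
Axis_Angle_Z_CAL	−0.54	−0.58	−0.70	−0.63
Quaternion_0_CAL	1.00	1.00	1.00	1.00
Quaternion_1_CAL	0.00	0.00	0.00	0.01
Quaternion_2_CAL	0.03	0.03	0.03	0.03
Quaternion_3_CAL	−0.02	−0.02	−0.03	−0.02
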