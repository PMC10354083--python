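SAMPLING EVENT IDENTIFIER	SPECIES CODE	OBSERVATION COUNT	LATITUDE	LONGITUDE	OBSERVATION DATE	TIME OBSERVATIONS STARTED	DURATION MINUTES	EFFORT DISTANCE KM	NUMBER OBSERVERS	PROTOCOL TYPE	ALL SPECIES REPORTED
S0000001	sp00	2	5.0	5.0	2015-03-10	07:30:00	60	1.2	1	Traveling	1
S0000002	sp00	1	4.0	6.0	2016-06-01	08:00:00	300	5.0	2	Traveling	1
S0000003	sp00	X	3.5	2.5	2010-01-01	06:45:00	45	0	1	Stationary	1
S0000004	sp00	4	6.2	7.1	2021-06-30	09:15:00	120	3.3	3	Traveling	1
S0000005	sp00	1	1.0	1.0	2018-11-23	16:00:00	30	0	1	Stationary	1
S0000006	sp00	3	9.0	9.0	2019-04-18	05:50:00	90	2.0	2	Birdlife Australia 500m radius search	1
S0000007	sp00	2	5.5	4.5	2017-02-14	07:00:00	60	1.0	1	Traveling	0
S0000008	sp00	1	2.0	8.0	2015-09-09	10:30:00	40	0	1	Incidental	1
S0000009	sp00	5	7.0	3.0	2014-05-05	06:20:00	301	2.5	2	Traveling	1
S0000010	sp00	1	8.0	2.0	2013-12-12	07:40:00	100	5.1	1	Traveling	1
S0000011	sp00	2	3.0	3.0	2009-12-31	08:10:00	50	1.5	1	Traveling	1
S0000012	sp00	1	50.0	50.0	2016-08-08	07:05:00	70	1.0	2	Traveling	1
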