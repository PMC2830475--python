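# Pak2 catalytic-domain residues mapped onto Pak1 structure numbering.
# Constant +21 offset across the catalytic domain (Pak2 Thr402 = Pak1 Thr423,
# Pak2 Lys278 = Pak1 Lys299); Pak1's extra N-terminal residues make the
# offset region dependent, so this table is limited to residues 249-500.
anchor_residue	structure_residue
249	270
250	271
251	272
252	273
253	274
254	275
255	276
256	277
257	278
258	279
259	280
260	281
261	282
262	283
263	284
264	285
265	286
266	287
267	288
268	289
269	290
270	291
271	292
272	293
273	294
274	295
275	296
276	297
277	298
278	299
279	300
280	301
281	302
282	303
283	304
284	305
285	306
286	307
287	308
288	309
289	310
290	311
291	312
292	313
293	314
294	315
295	316
296	317
297	318
298	319
299	320
300	321
301	322
302	323
303	324
304	325
305	326
306	327
307	328
308	329
309	330
310	331
311	332
312	333
313	334
314	335
315	336
316	337
317	338
318	339
319	340
320	341
321	342
322	343
323	344
324	345
325	346
326	347
327	348
328	349
329	350
330	351
331	352
332	353
333	354
334	355
335	356
336	357
337	358
338	359
339	360
340	361
341	362
342	363
343	364
344	365
345	366
346	367
347	368
348	369
349	370
350	371
351	372
352	373
353	374
354	375
355	376
356	377
357	378
358	379
359	380
360	381
361	382
362	383
363	384
364	385
365	386
366	387
367	388
368	389
369	390
370	391
371	392
372	393
373	394
374	395
375	396
376	397
377	398
378	399
379	400
380	401
381	402
382	403
383	404
384	405
385	406
386	407
387	408
388	409
389	410
390	411
391	412
392	413
393	414
394	415
395	416
396	417
397	418
398	419
399	420
400	421
401	422
402	423
403	424
404	425
405	426
406	427
407	428
408	429
409	430
410	431
411	432
412	433
413	434
414	435
415	436
416	437
417	438
418	439
419	440
420	441
421	442
422	443
423	444
424	445
425	446
426	447
427	448
428	449
429	450
430	451
431	452
432	453
433	454
434	455
435	456
436	457
437	458
438	459
439	460
440	461
441	462
442	463
443	464
444	465
445	466
446	467
447	468
448	469
449	470
450	471
451	472
452	473
453	474
454	475
455	476
456	477
457	478
458	479
459	480
460	481
461	482
462	483
463	484
464	485
465	486
466	487
467	488
468	489
469	490
470	491
471	492
472	493
473	494
474	495
475	496
476	497
477	498
478	499
479	500
480	501
481	502
482	503
483	504
484	505
485	506
486	507
487	508
488	509
489	510
490	511
491	512
492	513
493	514
494	515
495	516
496	517
497	518
498	519
499	520
500	521
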